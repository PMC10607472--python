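"""Packaged laboratory datasets and published parameter sets.

Everything another module needs to reproduce the published desk-scale
numbers ships here as plain CSV/YAML inside the package: the 17 pupal
temperature/development-time pairs (Eckenrode, Ishikawa and Park series),
the fitted Phase I/II parameter tables, the stage degree-day constants,
the stage lower thresholds behind the common base temperature, and the
1986/1987 percentile-matched emergence validation table. File contents are
checksummed at load so silent drift is caught immediately.
"""

from __future__ import annotations

import hashlib
from importlib import resources

import pandas as pd
import yaml

from .degree_days import StageConstants, common_base_temperature, thermal_constant
from .evaluation import report_from_percentile_dates
from .thermal_models import (
    CompletionDistribution,
    ThermalResponseParams,
    fit_lactin,
    lactin_upper_limit,
    weibull_cdf,
)

__all__ = ["FIXTURE_NAMES", "load_fixture", "fixture_path", "run_published_scenarios"]

_CHECKSUMS = {
    "pupal_development_points.csv": "06dc8c3693ac5b1d357a364f79f50a53c2cce1b2d774db917935d1f19d12e0e0",
    "params.yml": "e647ac0856517a6852d1488c2d1700be5810af45d1557f6160d3fbdf8f0720d6",
    "stage_dd_constants.csv": "6afd725baf9a269e2a43b124e416f064375a1a826741b53d31ce55c29f34f050",
    "table3_emergence.csv": "bc114f9b013ada8cd0e65674a84fa3c6ee304a56b8cb8011e2d58eaccbfdc6ef",
}

FIXTURE_NAMES = (
    "pupal_development_points",
    "table1_params",
    "table2_params",
    "stage_dd_constants",
    "lower_thresholds",
    "table3_1986",
    "table3_1987",
)


def fixture_path(filename: str):
    return resources.files("onionfly.data") / filename


def _read_bytes(filename: str) -> bytes:
    data = fixture_path(filename).read_bytes()
    expected = _CHECKSUMS.get(filename)
    if expected is not None:
        digest = hashlib.sha256(data).hexdigest()
        if digest != expected:
            raise RuntimeError(
                f"fixture {filename} content drifted (sha256 {digest[:12]}…)"
            )
    return data


def _params_doc() -> dict:
    return yaml.safe_load(_read_bytes("params.yml"))


def _phase_params(phase: str) -> dict:
    doc = _params_doc()[phase]
    return {
        "lactin": ThermalResponseParams(
            rho=doc["lactin"]["rho"],
            t_max=doc["lactin"]["t_max"],
            delta_t=doc["lactin"]["delta_t"],
        ),
        "weibull": CompletionDistribution(
            alpha=doc["weibull"]["alpha"], beta=doc["weibull"]["beta"]
        ),
    }


def load_fixture(name: str):
    """Return a packaged dataset by name; raises KeyError for unknown names."""
    import io

    if name == "pupal_development_points":
        return pd.read_csv(io.BytesIO(_read_bytes("pupal_development_points.csv")))
    if name == "table1_params":
        return _phase_params("sdt")
    if name == "table2_params":
        return _phase_params("pupal")
    if name == "stage_dd_constants":
        df = pd.read_csv(io.BytesIO(_read_bytes("stage_dd_constants.csv")))
        dd = dict(zip(df["stage"], df["degree_days"]))
        t_cb = _params_doc()["degree_days"]["t_cb"]
        return StageConstants(t_cb=t_cb, **dd)
    if name == "lower_thresholds":
        return list(_params_doc()["degree_days"]["lower_thresholds"])
    if name in ("table3_1986", "table3_1987"):
        df = pd.read_csv(io.BytesIO(_read_bytes("table3_emergence.csv")))
        year = int(name.rsplit("_", 1)[1])
        return df[df["year"] == year].reset_index(drop=True)
    raise KeyError(f"unknown fixture {name!r}; available: {FIXTURE_NAMES}")


def _scenarios() -> dict:
    """Desk-scale scenario definitions: name -> (compute, expected, tolerance)."""

    def lactin_refit():
        df = load_fixture("pupal_development_points")
        obs = list(zip(df["temperature_c"], 1.0 / df["development_days"]))
        return fit_lactin(obs)

    return {
        "common_base_temperature": (
            lambda: common_base_temperature(load_fixture("lower_thresholds")),
            3.9,
            1e-9,
        ),
        "egg_to_egg_dd": (
            lambda: load_fixture("stage_dd_constants").egg_to_egg,
            650.9,
            1e-6,
        ),
        "emergence_to_pupation_dd": (
            lambda: load_fixture("stage_dd_constants").emergence_to_pupation,
            433.9,
            1e-6,
        ),
        "backtrack_dd": (
            lambda: load_fixture("stage_dd_constants").backtrack_constant(),
            414.8,
            1e-6,
        ),
        "one_day_23c_dd": (
            lambda: thermal_constant(1.0, 23.0, load_fixture("stage_dd_constants").t_cb),
            19.1,
            1e-6,
        ),
        "pupal_lactin_r2": (lambda: lactin_refit().r_squared, 0.94, 0.01),
        "pupal_lactin_t_max": (lambda: lactin_refit().params.t_max, 37.89, 1.0),
        "sdt_upper_limit": (
            lambda: lactin_upper_limit(load_fixture("table1_params")["lactin"]),
            22.1,
            0.05,
        ),
        "sdt_completion_at_alpha_pct": (
            lambda: 100.0
            * weibull_cdf(
                load_fixture("table1_params")["weibull"].alpha,
                load_fixture("table1_params")["weibull"],
            ),
            63.2,
            0.05,
        ),
        "emergence_1986_mean_diff": (
            lambda: _table3_report(1986).mean_difference,
            7.64,
            0.005,
        ),
        "emergence_1986_se": (lambda: _table3_report(1986).se, 0.7296, 0.0001),
        "emergence_1987_mean_diff": (
            lambda: _table3_report(1987).mean_difference,
            4.79,
            0.005,
        ),
    }


def _table3_report(year: int):
    df = load_fixture(f"table3_{year}")
    return report_from_percentile_dates(
        df["percentile"], df["observed_julian"], df["predicted_julian"], null_days=5.0
    )


def run_published_scenarios(names=None) -> pd.DataFrame:
    """Recompute the published desk-scale numbers; report computed vs expected.

    Failures are reported in the ``passed`` column, never raised.
    """
    defs = _scenarios()
    if names is None:
        names = list(defs)
    rows = []
    for name in names:
        compute, expected, tol = defs[name]
        try:
            value = float(compute())
            passed = abs(value - expected) <= tol
            error = ""
        except Exception as exc:  # pragma: no cover - defensive
            value, passed, error = float("nan"), False, str(exc)
        rows.append(
            {
                "scenario": name,
                "computed": value,
                "expected": expected,
                "tolerance": tol,
                "passed": passed,
                "error": error,
            }
        )
    return pd.DataFrame(rows, columns=["scenario", "computed", "expected", "tolerance", "passed", "error"])
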