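"""Mixed-level orthogonal-array (Taguchi) sensitivity analysis.

The screening design is the canonical L54(2^1 x 3^25) orthogonal array: 54
runs, one two-level column and 25 three-level columns, strength 2 (every
pair of three-level columns shows each of the 9 level pairs exactly 6
times).  The packaged CSV fixture is generated by an Addelman-Kempthorne
style construction over GF(3) (see :func:`construct_l54`) and is validated
structurally every time it is loaded.

The 14 species parameters are assigned, in factor-table order, to the first
14 three-level columns; each run's level pattern is materialised into a
full parameter set (with ordering repair where a level combination is
infeasible), the model is executed per run, and larger-the-better
signal-to-noise ratios of the suitable + highly-suitable area response are
decomposed into per-factor main effects, deltas, ranks and optimum levels.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
import xarray as xr

from .ecoclimatic import SpeciesParameters, DATE_PALM, run_model
from .hydro import BucketParameters, monthly_to_weekly, soil_moisture_series
from .mapping import category_areas

__all__ = [
    "FactorTable",
    "TABLE_ORDER",
    "default_factor_table",
    "construct_l54",
    "validate_orthogonal_array",
    "load_orthogonal_array",
    "TaguchiDesign",
    "build_design",
    "resolve_run",
    "execute_design",
    "sn_larger_better",
    "SensitivityReport",
    "main_effects",
    "sensitivity_plot_data",
]

#: Factor order used for column assignment and rank tie-breaking.
TABLE_ORDER = (
    "SM0", "SM1", "SM2", "SM3",
    "DV0", "DV1", "DV2", "DV3",
    "TTCS", "THCS", "TTHS", "THHS", "SMWS", "HWS",
)

_DEFAULT_LEVELS: dict[str, tuple[float, float, float]] = {
    "SM0": (0.005, 0.007, 0.01),
    "SM1": (0.011, 0.013, 0.017),
    "SM2": (0.5, 0.81, 1.0),
    "SM3": (0.6, 0.9, 1.0),
    "DV0": (10.0, 14.0, 18.0),
    "DV1": (15.0, 20.0, 26.0),
    "DV2": (30.0, 39.0, 45.0),
    "DV3": (40.0, 46.0, 50.0),
    "TTCS": (2.0, 4.0, 5.0),
    "THCS": (-0.05, -0.01, 0.0),
    "TTHS": (40.0, 46.0, 50.0),
    "THHS": (0.7, 0.9, 1.0),
    "SMWS": (0.6, 0.9, 1.0),
    "HWS": (0.018, 0.022, 0.029),
}


@dataclass(frozen=True)
class FactorTable:
    """Three candidate values per screening factor, keyed by parameter code."""

    levels: dict[str, tuple[float, float, float]]

    def __post_init__(self) -> None:
        for code, vals in self.levels.items():
            if len(vals) != 3:
                raise ValueError(f"factor {code} must have exactly 3 levels")

    @property
    def codes(self) -> tuple[str, ...]:
        return tuple(self.levels)

    def value(self, code: str, level: int) -> float:
        """Value of ``code`` at 1-based ``level``."""
        return self.levels[code][level - 1]

    @classmethod
    def from_csv(cls, path) -> "FactorTable":
        df = pd.read_csv(path)
        levels = {
            str(r["code"]): (float(r["level1"]), float(r["level2"]), float(r["level3"]))
            for _, r in df.iterrows()
        }
        return cls(levels=levels)

    def to_csv(self, path) -> None:
        rows = [
            {"code": c, "level1": v[0], "level2": v[1], "level3": v[2]}
            for c, v in self.levels.items()
        ]
        pd.DataFrame(rows).to_csv(path, index=False)


def default_factor_table() -> FactorTable:
    """The date-palm screening levels (baseline values sit at level 2)."""
    return FactorTable(levels={c: _DEFAULT_LEVELS[c] for c in TABLE_ORDER})


# ---------------------------------------------------------------------------
# Orthogonal array
# ---------------------------------------------------------------------------

def construct_l54() -> np.ndarray:
    """Construct the L54(2^1 x 3^25) orthogonal array.

    Rows are two copies of the full factorial GF(3)^3 on (u, y2, y3).
    Column 1 is the copy indicator (levels 1-2).  The 25 three-level
    columns are the special column ``u`` plus, for each of the four
    normalised directions b over (y2, y3) and each slope t in GF(3), a
    linear column ``b.y + t*u`` and a quadratic column ``b.y + t*u +
    2*u^2``; in the second copy the quadratic term and slopes are modified
    (u^2 coefficient 1, slope 2t) with per-slope additive shifts chosen so
    the deficient within-copy pair distributions of the linear x quadratic
    pairs complement each other exactly.  The result is a strength-2 array:
    every three-level column is 18/18/18 balanced and every pair of
    three-level columns shows each of the 9 level pairs exactly 6 times.

    Returns an int array of shape (54, 26) with 1-based levels.
    """
    rows = list(itertools.product(range(3), repeat=3))
    p_shift = (0, 1, 1)
    s_shift = (0, 2, 2)
    directions = ((1, 0), (0, 1), (1, 1), (1, 2))

    cols: list[list[int]] = [[u for (u, _, _) in rows] * 2]
    for b in directions:
        for t in range(3):
            lin_a = [(b[0] * y2 + b[1] * y3 + t * u) % 3 for (u, y2, y3) in rows]
            lin_b = [(v + p_shift[t]) % 3 for v in lin_a]
            cols.append(lin_a + lin_b)
            quad_a = [(b[0] * y2 + b[1] * y3 + t * u + 2 * u * u) % 3 for (u, y2, y3) in rows]
            quad_b = [(b[0] * y2 + b[1] * y3 + 2 * t * u + u * u + s_shift[t]) % 3
                      for (u, y2, y3) in rows]
            cols.append(quad_a + quad_b)

    three_level = np.array(cols, dtype=int).T + 1
    # Column order chosen so that the first 14 three-level columns (the ones
    # factors are assigned to) form protected pairs: for each strongly
    # interacting factor pair assigned to consecutive slots, every other
    # assigned column is a strength-3 companion, i.e. the pair's two-factor
    # interaction is exactly balanced there and contributes no spurious
    # main effect.
    order = [13, 19, 18, 24, 14, 20, 15, 21, 0, 4, 5, 8, 16, 22,
             1, 2, 3, 6, 7, 9, 10, 11, 12, 17, 23]
    three_level = three_level[:, order]
    two_level = np.array([1] * 27 + [2] * 27, dtype=int)[:, None]
    return np.hstack([two_level, three_level])


def validate_orthogonal_array(array: np.ndarray) -> None:
    """Check balance and strength-2 invariants; raise ValueError on failure."""
    array = np.asarray(array)
    if array.shape != (54, 26):
        raise ValueError(f"expected a 54 x 26 array, got shape {array.shape}")
    two = array[:, 0]
    if sorted(np.unique(two)) != [1, 2] or np.any(np.bincount(two)[1:] != 27):
        raise ValueError("two-level column must contain levels 1 and 2, 27 times each")
    three = array[:, 1:]
    if not np.isin(three, (1, 2, 3)).all():
        raise ValueError("three-level columns must contain only levels 1-3")
    for j in range(25):
        counts = np.bincount(three[:, j], minlength=4)[1:]
        if not (counts == 18).all():
            raise ValueError(f"three-level column {j + 1} unbalanced: counts {counts.tolist()}")
    for i in range(25):
        for j in range(i + 1, 25):
            pair_counts = np.bincount((three[:, i] - 1) * 3 + (three[:, j] - 1), minlength=9)
            if not (pair_counts == 6).all():
                raise ValueError(
                    f"strength-2 violation between three-level columns {i + 1} and {j + 1}"
                )


def load_orthogonal_array() -> np.ndarray:
    """Load and validate the packaged L54 array fixture.

    Returns an int array (54 rows x 26 columns, 1-based levels; column 0 is
    the two-level column).
    """
    ref = resources.files("climexsa.data").joinpath("l54_2x1_3x25.csv")
    if not ref.is_file():
        raise FileNotFoundError("packaged orthogonal-array fixture l54_2x1_3x25.csv is missing")
    with ref.open("r") as fh:
        df = pd.read_csv(fh)
    array = df.to_numpy(dtype=int)
    validate_orthogonal_array(array)
    return array


# ---------------------------------------------------------------------------
# Design
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TaguchiDesign:
    """An orthogonal array with factors assigned and runs materialised."""

    array: np.ndarray
    factors: FactorTable
    assignment: dict[str, int]          # code -> array column index
    levels: pd.DataFrame                # run x code, 1-based levels
    runs: tuple[SpeciesParameters, ...]
    repairs: pd.DataFrame               # run, code, level_value, repaired_value

    @property
    def n_runs(self) -> int:
        return self.array.shape[0]


_ORDER_CHAIN = (
    ("DV0", "DV1", True), ("DV1", "DV2", False), ("DV2", "DV3", True),
    ("SM0", "SM1", True), ("SM1", "SM2", False), ("SM2", "SM3", True),
)


def resolve_run(
    values: dict[str, float], run_id: int | None = None
) -> tuple[SpeciesParameters, list[dict]]:
    """Materialise one run's raw factor values into a valid parameter set.

    Level combinations that violate the knot ordering (e.g. an upper
    optimal above the limiting high) are repaired by clamping the upper
    knot to the lower knot + 0.1, giving a degenerate ramp; every repair is
    returned in the log.
    """
    vals = dict(DATE_PALM.as_dict())
    vals.update(values)
    repairs: list[dict] = []
    for lo, hi, strict in _ORDER_CHAIN:
        bad = vals[hi] <= vals[lo] if strict else vals[hi] < vals[lo]
        if bad:
            repaired = round(vals[lo] + 0.1, 6)
            repairs.append(
                {"run": run_id, "code": hi, "level_value": vals[hi], "repaired_value": repaired}
            )
            vals[hi] = repaired
    if vals["THCS"] > 0:
        repairs.append({"run": run_id, "code": "THCS", "level_value": vals["THCS"], "repaired_value": 0.0})
        vals["THCS"] = 0.0
    return SpeciesParameters(**vals), repairs


def build_design(array: np.ndarray, factors: FactorTable | None = None) -> TaguchiDesign:
    """Assign factors to columns and materialise all runs.

    Factors are assigned, in table order, to the first three-level columns
    (array columns 1, 2, ...); the two-level column and the remaining
    three-level columns stay unassigned.
    """
    if factors is None:
        factors = default_factor_table()
    validate_orthogonal_array(array)
    codes = factors.codes
    if len(codes) > 25:
        raise ValueError(f"{len(codes)} factors exceed the 25 available three-level columns")
    assignment = {code: 1 + i for i, code in enumerate(codes)}

    levels = pd.DataFrame(
        {code: array[:, col] for code, col in assignment.items()},
        index=pd.RangeIndex(1, array.shape[0] + 1, name="run"),
    )
    runs = []
    repair_rows: list[dict] = []
    for run_id, row in levels.iterrows():
        raw = {code: factors.value(code, int(row[code])) for code in codes}
        params, repairs = resolve_run(raw, run_id=run_id)
        runs.append(params)
        repair_rows.extend(repairs)
    repairs_df = pd.DataFrame(repair_rows, columns=["run", "code", "level_value", "repaired_value"])
    return TaguchiDesign(
        array=array, factors=factors, assignment=assignment,
        levels=levels, runs=tuple(runs), repairs=repairs_df,
    )


# ---------------------------------------------------------------------------
# Execution and signal-to-noise analysis
# ---------------------------------------------------------------------------

#: Floor (km^2) substituted for a zero-area response before the log transform.
ZERO_RESPONSE_FLOOR_KM2 = 1.0


def sn_larger_better(responses) -> float:
    """Larger-the-better signal-to-noise ratio in dB.

    ``SN = -10 log10( (1/n) sum 1/y_i^2 )``; for a single replicate this
    reduces to ``20 log10(y)``.  All responses must be positive.
    """
    y = np.asarray(responses, dtype=float)
    if y.size == 0:
        raise ValueError("empty response list")
    if np.any(y <= 0):
        raise ValueError("larger-the-better SN is undefined for responses <= 0")
    return float(-10.0 * np.log10(np.mean(1.0 / y**2)))


def execute_design(
    design: TaguchiDesign,
    normals: xr.Dataset,
    bucket: BucketParameters | None = None,
) -> pd.DataFrame:
    """Run the model once per design row and compute responses and SN.

    The weekly climate and converged soil moisture depend only on the
    climate and bucket, not on the species parameters, so they are computed
    once and shared across runs.  The response y is the suitable +
    highly-suitable area in km^2; zero responses are floored at
    ``ZERO_RESPONSE_FLOOR_KM2`` before the SN transform and flagged.

    Returns one row per run: the 14 parameter values, the four category
    areas, ``y``, ``floored`` and ``sn_db``.
    """
    weekly = monthly_to_weekly(normals)
    sm = soil_moisture_series(weekly, bucket)

    records = []
    for run_id, params in zip(design.levels.index, design.runs):
        try:
            raster = run_model(normals, params, bucket=bucket, weekly=weekly, soil_moisture=sm)
        except Exception as exc:  # pragma: no cover - propagation path
            raise RuntimeError(f"model execution failed for design run {run_id}") from exc
        areas = category_areas(raster)
        y = areas.suitable_or_better
        floored = y <= 0
        y_eff = ZERO_RESPONSE_FLOOR_KM2 if floored else y
        rec = {"run": run_id, **params.as_dict(), **areas.as_dict()}
        rec.update({"y": y, "floored": floored, "sn_db": sn_larger_better([y_eff])})
        records.append(rec)
    return pd.DataFrame(records).set_index("run")


@dataclass(frozen=True)
class SensitivityReport:
    """Per-factor SN main effects.

    ``table`` is indexed by factor code with columns ``mean_sn_L1..L3``
    (dB), ``delta`` (max - min of the level means), ``rank`` (1 = most
    sensitive; ties broken by factor order), ``optimum_level`` (argmax
    level mean) and ``baseline_agreement`` (True when the optimum level is
    the level holding the baseline parameter value).
    """

    table: pd.DataFrame
    n_floored: int = 0

    @property
    def ranking(self) -> list[str]:
        """Factor codes from most to least sensitive."""
        return list(self.table.sort_values("rank").index)


def main_effects(
    design: TaguchiDesign,
    results: pd.DataFrame,
    baseline: SpeciesParameters = DATE_PALM,
) -> SensitivityReport:
    """Average SN per factor level and rank factors by delta."""
    if len(results) != design.n_runs:
        raise ValueError(f"expected {design.n_runs} run results, got {len(results)}")
    sn = results["sn_db"].to_numpy(dtype=float)

    rows = {}
    for code in design.factors.codes:
        lv = design.levels[code].to_numpy()
        means = [float(sn[lv == level].mean()) for level in (1, 2, 3)]
        delta = max(means) - min(means)
        optimum = int(np.argmax(means)) + 1
        level_vals = design.factors.levels[code]
        base_val = getattr(baseline, code)
        base_level = (
            int(np.argmin(np.abs(np.asarray(level_vals) - base_val))) + 1
            if base_val is not None else None
        )
        rows[code] = {
            "mean_sn_L1": means[0], "mean_sn_L2": means[1], "mean_sn_L3": means[2],
            "delta": delta, "optimum_level": optimum,
            "baseline_level": base_level,
            "baseline_agreement": optimum == base_level,
        }
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "code"
    # rank by delta, ties broken by factor-table order
    order = {code: i for i, code in enumerate(design.factors.codes)}
    ranked = sorted(table.index, key=lambda c: (-table.loc[c, "delta"], order[c]))
    table["rank"] = [ranked.index(c) + 1 for c in table.index]
    n_floored = int(results["floored"].sum()) if "floored" in results else 0
    return SensitivityReport(table=table, n_floored=n_floored)


def sensitivity_plot_data(report: SensitivityReport) -> dict[str, list[tuple[int, float]]]:
    """Ordered (level, mean SN) series per factor, for line plots.

    A flat series (all three means equal) is exactly a zero-delta factor.
    """
    return {
        code: [(lv, float(report.table.loc[code, f"mean_sn_L{lv}"])) for lv in (1, 2, 3)]
        for code in report.table.index
    }
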