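"""The 630-condition parametric sweep and its summary statistics.

The grid crosses relief peak height (0/1/2 m), wind coefficient (−1.5…1.5 in
steps of 0.5), translational optic-flow setpoint (2.0…3.5 rad s⁻¹ in steps of
0.3) and cruise pitch (30°…50° in steps of 5°): 3·7·6·5 = 630 full 100 m
flights.  Each condition yields the final ground-truth distance and both
odometer outputs; summaries compare the dispersion of the self-scaled
odometer against the calibrated raw accumulator with the median absolute
deviation (MAD), the Brown–Forsythe dispersion test, a Kruskal–Wallis test of
the raw accumulator across wind classes, and per-wind-class rank-sum tests
between the two models.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .config import ScenarioConfig
from .odometry import k_comparisons
from .scenarios import long_course_100m
from .simulate import simulate

__all__ = ["SweepSummary", "build_grid", "run_sweep", "mad", "rmad", "summarize"]

H_PEAK_LEVELS = (0.0, 1.0, 2.0)
K_WIND_LEVELS = (-1.5, -1.0, -0.5, 0.0, 0.5, 1.0, 1.5)
OMEGA_SET_LEVELS = (2.0, 2.3, 2.6, 2.9, 3.2, 3.5)
PITCH_LEVELS = (30.0, 35.0, 40.0, 45.0, 50.0)


def build_grid(
    h_peak_levels=H_PEAK_LEVELS,
    k_wind_levels=K_WIND_LEVELS,
    omega_set_levels=OMEGA_SET_LEVELS,
    pitch_levels=PITCH_LEVELS,
    f_osc: float = 1.0,
) -> list[ScenarioConfig]:
    """Cartesian product of the sweep factors as fully-specified scenarios."""
    grid = []
    for h_peak, k_wind, w_set, pitch in itertools.product(
        h_peak_levels, k_wind_levels, omega_set_levels, pitch_levels
    ):
        cfg = long_course_100m(k_wind=k_wind, h_peak=h_peak)
        grid.append(
            cfg.with_overrides(
                controller__omega_T_set=w_set,
                controller__f_osc=f_osc,
                mission__u_theta_cruise=pitch,
            )
        )
    return grid


def run_sweep(grid: list[ScenarioConfig], seed: int | None = None) -> pd.DataFrame:
    """Run every condition of the grid; one record per condition.

    Deterministic: identical re-runs produce identical records.  Diverged
    runs (safety cap exceeded) are flagged in the ``diverged`` column, never
    dropped.
    """
    res = simulate(grid, record=False, seed=seed)
    return res.records


def mad(values) -> float:
    """Median absolute deviation, ``median(|v − median(v)|)``, no scaling."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("mad of an empty sequence")
    return float(np.median(np.abs(values - np.median(values))))


def rmad(values) -> float:
    """Relative MAD: the ratio of the MAD to the median."""
    values = np.asarray(values, dtype=float)
    return mad(values) / float(np.median(values))


def _wind_class(k_wind: pd.Series) -> pd.Series:
    return pd.Series(
        np.where(k_wind > 0, "tail", np.where(k_wind < 0, "head", "none")),
        index=k_wind.index,
    )


@dataclass
class SweepSummary:
    """Headline statistics of one sweep (distances in m unless noted)."""

    n_records: int
    k_comparisons: float
    sofia_median: float
    sofia_mad: float
    sofia_rmad: float
    ofacc_median_rad: float
    ofacc_mad_rad: float
    ofacc_cal_median: float
    ofacc_cal_mad: float
    ofacc_cal_rmad: float
    per_wind: dict = field(default_factory=dict)
    dispersion_test: dict = field(default_factory=dict)
    kruskal_ofacc_wind: dict = field(default_factory=dict)
    ranksum_per_wind: dict = field(default_factory=dict)
    max_h: float = float("nan")
    max_V_x: float = float("nan")
    max_abs_v_wind: float = float("nan")

    def to_dict(self) -> dict:
        import dataclasses

        return dataclasses.asdict(self)


def summarize(records: pd.DataFrame) -> SweepSummary:
    """Compute medians/MADs/rMADs, the calibration factor and the tests.

    The raw-accumulator distribution is multiplied by the sweep's own
    calibration factor (so its overall median maps to 100 m by construction)
    before any comparison in metres.  Wind classes follow the sign of the
    wind coefficient.  Degenerate classes are reported as missing entries,
    not errors.
    """
    if len(records) < 2:
        raise ValueError("need at least two records to summarize")
    ok = records[~records["diverged"]]
    kcomp = k_comparisons(ok["of_acc"])
    sofia = ok["x_sofia"].to_numpy()
    ofacc = ok["of_acc"].to_numpy()
    ofacc_cal = ofacc * kcomp

    wind_class = _wind_class(ok["k_wind"])
    per_wind: dict[str, dict] = {}
    ranksum: dict[str, dict] = {}
    for cls in ("tail", "none", "head"):
        sel = wind_class == cls
        if sel.sum() < 2:
            per_wind[cls] = None
            ranksum[cls] = None
            continue
        s = sofia[sel.to_numpy()]
        o = ofacc_cal[sel.to_numpy()]
        per_wind[cls] = {
            "n": int(sel.sum()),
            "sofia_median": float(np.median(s)),
            "sofia_mad": mad(s),
            "ofacc_cal_median": float(np.median(o)),
            "ofacc_cal_mad": mad(o),
        }
        z, p = sps.ranksums(s, o)
        ranksum[cls] = {"z": float(z), "p": float(p)}

    # Brown–Forsythe: Levene's test on absolute deviations from the median
    F, p = sps.levene(sofia, ofacc_cal, center="median")
    dispersion = {
        "F": float(F),
        "p": float(p),
        "df": (1, int(len(sofia) + len(ofacc_cal) - 2)),
    }

    classes = [ofacc_cal[(wind_class == c).to_numpy()] for c in ("tail", "none", "head")]
    classes = [c for c in classes if len(c) >= 2]
    if len(classes) >= 2:
        H, pk = sps.kruskal(*classes)
        kruskal = {"H": float(H), "p": float(pk)}
    else:
        kruskal = {"H": float("nan"), "p": float("nan")}

    return SweepSummary(
        n_records=int(len(ok)),
        k_comparisons=kcomp,
        sofia_median=float(np.median(sofia)),
        sofia_mad=mad(sofia),
        sofia_rmad=rmad(sofia),
        ofacc_median_rad=float(np.median(ofacc)),
        ofacc_mad_rad=mad(ofacc),
        ofacc_cal_median=float(np.median(ofacc_cal)),
        ofacc_cal_mad=mad(ofacc_cal),
        ofacc_cal_rmad=rmad(ofacc_cal),
        per_wind=per_wind,
        dispersion_test=dispersion,
        kruskal_ofacc_wind=kruskal,
        ranksum_per_wind=ranksum,
        max_h=float(ok["max_h"].max()),
        max_V_x=float(ok["max_V_x"].max()),
        max_abs_v_wind=float(ok["max_abs_v_wind"].max()),
    )
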