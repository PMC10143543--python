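"""Cross-system method agreement: case filtering, range scaling,
outlier flagging, Pearson correlation, ICC(3,1) and Bland-Altman
limits of agreement.

The insole system is treated as the reference axis: IMU feature values
are min-max scaled onto the range observed for the corresponding insole
feature, and differences are signed insole - IMU.  The intraclass
correlation uses the two-way mixed, single-rater, consistency form
("single fixed raters"):

    ICC(3,1) = (MSR - MSE) / (MSR + (k - 1) MSE),   k = 2 systems,

reported pooled over all retained sessions (headline) and stratified by
instructed walking speed.  Bland-Altman limits are mean +/- 1.96 * SD of
the paired differences.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

#: (report name, insole session column, IMU session column)
COMMON_FEATURES: tuple[tuple[str, str, str], ...] = (
    ("walking_cadence", "a14_mean", "walking_cadence"),
    ("right_gait_cycle_duration", "a09_mean", "cycle_duration_mean_right"),
    ("left_gait_cycle_duration", "a13_mean", "cycle_duration_mean_left"),
    ("right_single_support", "a01_mean", "single_support_right_mean"),
    ("left_single_support", "a02_mean", "single_support_left_mean"),
    ("right_side_stance_phase", "a04_mean", "stance_mean_right"),
    ("left_side_stance_phase", "a05_mean", "stance_mean_left"),
    ("number_of_steps", "number_of_steps", "number_of_steps"),
)


# ---------------------------------------------------------------------------
# case filtering and scaling
# ---------------------------------------------------------------------------

def exclude_low_step_cases(sessions: pd.DataFrame, min_steps: int = 3,
                           step_columns: tuple[str, str] = ("insole_steps",
                                                            "imu_steps")
                           ) -> tuple[pd.DataFrame, list[dict]]:
    """Drop sessions where either system counted fewer than ``min_steps``.

    The boundary is exclusive: exactly ``min_steps`` steps is retained.
    Returns the filtered table and an exclusion log.
    """
    log = []
    keep = pd.Series(True, index=sessions.index)
    for col in step_columns:
        low = sessions[col] < min_steps
        for idx in sessions.index[low & keep]:
            log.append({"session": sessions.loc[idx].get("session_id", idx),
                        "reason": f"{col}={sessions.loc[idx, col]} < {min_steps}"})
        keep &= ~low
    return sessions[keep].copy(), log


def scale_to_reference(imu_values: np.ndarray, insole_values: np.ndarray,
                       feature: str = "") -> tuple[np.ndarray, dict]:
    """Affine min-max map sending the IMU sample range onto the insole range."""
    imu_values = np.asarray(imu_values, float)
    insole_values = np.asarray(insole_values, float)
    lo_i, hi_i = np.nanmin(imu_values), np.nanmax(imu_values)
    lo_r, hi_r = np.nanmin(insole_values), np.nanmax(insole_values)
    if hi_i - lo_i <= 0:
        raise ValueError(f"cannot scale constant IMU sample for feature "
                         f"{feature or '<unnamed>'}")
    slope = (hi_r - lo_r) / (hi_i - lo_i)
    intercept = lo_r - slope * lo_i
    return slope * imu_values + intercept, {"slope": float(slope),
                                            "intercept": float(intercept)}


def flag_outliers(differences: np.ndarray, threshold: float = 3.0) -> np.ndarray:
    """Robust-z outlier mask on paired differences.

    Scale is the MAD (scaled to std of a normal); when the MAD
    degenerates to zero the sample std is used, and with no spread at
    all nothing is flagged.
    """
    d = np.asarray(differences, float)
    med = np.median(d)
    mad = np.median(np.abs(d - med)) * 1.4826
    scale = mad if mad > 0 else float(np.std(d, ddof=1)) if len(d) > 1 else 0.0
    if scale <= 0:
        return np.zeros(len(d), bool)
    return np.abs(d - med) / scale > threshold


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------

def pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Product-moment correlation of the paired feature values."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    if len(x) < 3:
        raise ValueError("Pearson correlation needs at least 3 pairs")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("Pearson correlation undefined for zero variance")
    return float(stats.pearsonr(x, y).statistic)


def icc_3_1(x: np.ndarray, y: np.ndarray) -> float:
    """ICC(3,1): two-way mixed, consistency, single rater, k = 2 raters.

    Computed from the two-way ANOVA mean squares of the n x 2 table
    whose rows are sessions (targets) and columns the two systems.
    Identical columns give exactly 1.
    """
    data = np.column_stack([np.asarray(x, float), np.asarray(y, float)])
    n, k = data.shape
    if n < 3:
        raise ValueError("ICC needs at least 3 pairs")
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    msr = k * np.sum((row_means - grand) ** 2) / (n - 1)
    resid = data - row_means[:, None] - col_means[None, :] + grand
    mse = np.sum(resid ** 2) / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse
    if denom == 0:
        return float("nan")
    return float((msr - mse) / denom)


def icc_single_fixed(x: np.ndarray, y: np.ndarray,
                     groups: np.ndarray | None = None
                     ) -> tuple[float, dict[str, float]]:
    """Pooled ICC(3,1) plus a per-group (walking speed) breakdown."""
    overall = icc_3_1(x, y)
    per_group: dict[str, float] = {}
    if groups is not None:
        groups = np.asarray(groups)
        for g in pd.unique(groups):
            m = groups == g
            if m.sum() >= 3:
                per_group[str(g)] = icc_3_1(np.asarray(x)[m], np.asarray(y)[m])
    return overall, per_group


@dataclass
class BlandAltman:
    mean_diff: float
    sd_diff: float
    loa_low: float
    loa_high: float


def bland_altman(x: np.ndarray, y: np.ndarray) -> BlandAltman:
    """Limits of agreement of the differences x - y (mean +/- 1.96 SD)."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    if len(x) < 3:
        raise ValueError("Bland-Altman analysis needs at least 3 pairs")
    d = x - y
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltman(mean_diff=mean, sd_diff=sd,
                       loa_low=mean - 1.96 * sd, loa_high=mean + 1.96 * sd)


# ---------------------------------------------------------------------------
# full comparison
# ---------------------------------------------------------------------------

@dataclass
class FeatureAgreement:
    feature: str
    pearson_r: float
    icc: float
    icc_per_speed: dict[str, float]
    bland_altman: BlandAltman
    n_cases: int
    n_outliers: int
    scaling: dict


@dataclass
class AgreementResult:
    features: list[FeatureAgreement]
    n_sessions_in: int
    n_excluded_low_steps: int
    exclusion_log: list[dict] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for f in self.features:
            rows.append({
                "feature": f.feature, "pearson_r": f.pearson_r, "icc": f.icc,
                **{f"icc_{k}": v for k, v in sorted(f.icc_per_speed.items())},
                "ba_mean_diff": f.bland_altman.mean_diff,
                "ba_sd_diff": f.bland_altman.sd_diff,
                "ba_loa_low": f.bland_altman.loa_low,
                "ba_loa_high": f.bland_altman.loa_high,
                "n_cases": f.n_cases, "n_outliers": f.n_outliers})
        return pd.DataFrame(rows)


def build_paired_table(insole_features: pd.DataFrame,
                       imu_features: pd.DataFrame,
                       manifest: pd.DataFrame) -> pd.DataFrame:
    """One row per session with both systems' values for each common feature.

    The feature tables must carry a ``session_id`` column matching the
    manifest's.
    """
    ins = insole_features.set_index("session_id")
    imu = imu_features.set_index("session_id")
    man = manifest.set_index("session_id")
    common = ins.index.intersection(imu.index).intersection(man.index)
    rows = {}
    rows["session_id"] = list(common)
    rows["subject_id"] = man.loc[common, "subject_id"].to_list()
    rows["speed"] = man.loc[common, "speed"].to_list()
    rows["insole_steps"] = ins.loc[common, "number_of_steps"].to_list()
    rows["imu_steps"] = imu.loc[common, "number_of_steps"].to_list()
    for name, ins_col, imu_col in COMMON_FEATURES:
        rows[f"insole_{name}"] = ins.loc[common, ins_col].to_list()
        rows[f"imu_{name}"] = imu.loc[common, imu_col].to_list()
    return pd.DataFrame(rows).reset_index(drop=True)


def compare_systems(paired: pd.DataFrame, min_steps: int = 3,
                    outlier_threshold: float = 3.0) -> AgreementResult:
    """Run the full agreement analysis on a paired session table.

    Per feature: scale the IMU values to the insole range, flag robust-z
    outliers on the differences (excluded from r and ICC, retained in
    the Bland-Altman statistics as in the source analysis's marked
    points), then compute Pearson r, pooled and per-speed ICC(3,1) and
    the Bland-Altman limits.
    """
    n_in = len(paired)
    retained, log = exclude_low_step_cases(paired, min_steps=min_steps)
    results = []
    for name, _, _ in COMMON_FEATURES:
        ins = retained[f"insole_{name}"].to_numpy(float)
        imu = retained[f"imu_{name}"].to_numpy(float)
        ok = np.isfinite(ins) & np.isfinite(imu)
        ins, imu = ins[ok], imu[ok]
        speeds = retained["speed"].to_numpy()[ok]
        scaled, scaling = scale_to_reference(imu, ins, feature=name)
        mask = flag_outliers(ins - scaled, threshold=outlier_threshold)
        r = pearson(ins[~mask], scaled[~mask])
        icc, per_speed = icc_single_fixed(ins[~mask], scaled[~mask],
                                          groups=speeds[~mask])
        ba = bland_altman(ins, scaled)
        results.append(FeatureAgreement(
            feature=name, pearson_r=r, icc=icc, icc_per_speed=per_speed,
            bland_altman=ba, n_cases=int((~mask).sum()),
            n_outliers=int(mask.sum()), scaling=scaling))
    return AgreementResult(features=results, n_sessions_in=n_in,
                           n_excluded_low_steps=n_in - len(retained),
                           exclusion_log=log)


def save_agreement_plots(paired: pd.DataFrame, result: AgreementResult,
                         out_dir) -> list[str]:
    """Scatter (with identity line) and Bland-Altman plot per feature."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for f in result.features:
        ins = paired[f"insole_{f.feature}"].to_numpy(float)
        imu = paired[f"imu_{f.feature}"].to_numpy(float)
        ok = np.isfinite(ins) & np.isfinite(imu)
        ins, imu = ins[ok], imu[ok]
        scaled, _ = scale_to_reference(imu, ins, feature=f.feature)
        mask = flag_outliers(ins - scaled)
        fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 4))
        ax1.scatter(ins[~mask], scaled[~mask], s=12)
        if mask.any():
            ax1.scatter(ins[mask], scaled[mask], marker="x", color="tab:orange")
        lim = [min(ins.min(), scaled.min()), max(ins.max(), scaled.max())]
        ax1.plot(lim, lim, "k--", lw=0.8)
        ax1.set_title(f"{f.feature} (r={f.pearson_r:.2f})")
        ax1.set_xlabel("insole")
        ax1.set_ylabel("IMU (scaled)")
        means, diffs = 0.5 * (ins + scaled), ins - scaled
        ax2.scatter(means, diffs, s=12)
        for yv in (f.bland_altman.mean_diff, f.bland_altman.loa_low,
                   f.bland_altman.loa_high):
            ax2.axhline(yv, color="tab:red", lw=0.8, ls="--")
        ax2.set_title("Bland-Altman")
        ax2.set_xlabel("mean of systems")
        ax2.set_ylabel("insole - IMU")
        fig.tight_layout()
        p = out / f"agreement_{f.feature}.png"
        fig.savefig(p, dpi=100)
        plt.close(fig)
        paths.append(str(p))
    return paths
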