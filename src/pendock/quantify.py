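"""Corrected total cell fluorescence (CTCF) and replicate-aware statistics.

CTCF quantifies per-cell fluorescence with local background subtraction:

    CTCF = integrated density - (cell area x mean background fluorescence)

where integrated density is the raw pixel sum over the cell ROI (ImageJ
RawIntDen semantics), area is in pixels and intensities stay in arbitrary
units.  Group summaries follow the SuperPlot convention (cell-level mean/SD
plus per-biological-replicate means and the mean +/- SD of those means), and
group comparisons use Student's t test (pooled variance, two-sided; Welch by
flag), the Mann-Whitney U test, or one-way ANOVA with Tukey HSD post hoc
tests.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class CellMeasurement:
    cell_id: str
    integrated_density: float
    area: float                      # pixels
    background_mean: float           # A.U. per pixel
    ctcf: float                      # A.U.
    replicate: str = "rep1"
    group: str = "group"

    def __post_init__(self) -> None:
        if self.area <= 0:
            raise ValueError("cell area must be positive")


def compute_ctcf(integrated_density: float, area: float, background_mean: float) -> float:
    """CTCF = integrated density - area x mean background (may be negative)."""
    if area <= 0:
        raise ValueError("cell area must be positive")
    return float(integrated_density) - float(area) * float(background_mean)


def measure_cell(
    image: np.ndarray,
    cell_mask: np.ndarray,
    background_masks: list[np.ndarray],
    cell_id: str = "cell",
    replicate: str = "rep1",
    group: str = "group",
) -> CellMeasurement:
    """Per-cell CTCF from an intensity image, a cell ROI and background ROIs.

    Integrated density is the raw pixel sum over the cell mask; the background
    mean is taken over the union of the (cell-disjoint) background masks.
    """
    image = np.asarray(image, dtype=float)
    cell_mask = np.asarray(cell_mask, dtype=bool)
    if cell_mask.shape != image.shape:
        raise ValueError("cell mask shape differs from image shape")
    if not cell_mask.any():
        raise ValueError("empty cell mask")
    bg_union = np.zeros_like(cell_mask)
    for m in background_masks:
        m = np.asarray(m, dtype=bool)
        if m.shape != image.shape:
            raise ValueError("background mask shape differs from image shape")
        if (m & cell_mask).any():
            raise ValueError("background mask overlaps the cell mask")
        bg_union |= m
    if not bg_union.any():
        raise ValueError("empty background masks")
    int_den = float(image[cell_mask].sum())
    area = float(cell_mask.sum())
    bg_mean = float(image[bg_union].mean())
    return CellMeasurement(cell_id, int_den, area, bg_mean,
                           compute_ctcf(int_den, area, bg_mean), replicate, group)


@dataclass
class GroupSummary:
    group: str
    n_cells: int
    mean: float
    sd: float
    replicate_means: dict[str, float] = field(default_factory=dict)
    mean_of_replicate_means: float = float("nan")
    sd_of_replicate_means: float = float("nan")

    @property
    def n_replicates(self) -> int:
        return len(self.replicate_means)


def summarize_superplot(measurements: list[CellMeasurement]) -> dict[str, GroupSummary]:
    """SuperPlot group summaries: cell-level and replicate-level statistics.

    SDs use the n-1 denominator; the SD of replicate means is reported when a
    group has at least two replicates (the convention is to display it for
    N > 2, but it is always computed here and labelled by replicate count).
    """
    if not measurements:
        raise ValueError("no measurements")
    df = pd.DataFrame(
        {
            "group": [m.group for m in measurements],
            "replicate": [m.replicate for m in measurements],
            "ctcf": [m.ctcf for m in measurements],
        }
    )
    out: dict[str, GroupSummary] = {}
    for group, sub in df.groupby("group", sort=True):
        rep_means = sub.groupby("replicate")["ctcf"].mean().to_dict()
        rep_values = np.array(list(rep_means.values()))
        out[group] = GroupSummary(
            group=group,
            n_cells=len(sub),
            mean=float(sub["ctcf"].mean()),
            sd=float(sub["ctcf"].std(ddof=1)) if len(sub) > 1 else 0.0,
            replicate_means=rep_means,
            mean_of_replicate_means=float(rep_values.mean()),
            sd_of_replicate_means=float(rep_values.std(ddof=1))
            if len(rep_values) > 1 else float("nan"),
        )
    return out


@dataclass(frozen=True)
class ComparisonResult:
    test: str
    statistic: float
    p_value: float
    mean_control: float
    mean_treatment: float
    fold_change: float           # mean_treatment / mean_control
    percent_change: float        # 100 * (fold - 1)

    @property
    def percent_change_rounded(self) -> int:
        return int(round(self.percent_change))


def compare_groups(
    control: np.ndarray,
    treatment: np.ndarray,
    test: str = "t",
    welch: bool = False,
) -> ComparisonResult:
    """Two-group comparison with fold and percent change (treatment vs control).

    ``test`` is 't' (Student's, pooled variance unless ``welch``) or
    'mannwhitney'.  Two groups of identical constant values compare with
    p = 1 by convention.
    """
    a = np.asarray(control, dtype=float)
    b = np.asarray(treatment, dtype=float)
    mean_c, mean_t = float(a.mean()), float(b.mean())
    fold = mean_t / mean_c if mean_c != 0 else float("inf")
    percent = 100.0 * (fold - 1.0) if np.isfinite(fold) else float("inf")
    if test == "t":
        if len(a) < 2 or len(b) < 2:
            raise ValueError("t test needs n >= 2 per group")
        if np.std(a) == 0 and np.std(b) == 0 and mean_c == mean_t:
            stat, p = 0.0, 1.0
        else:
            stat, p = stats.ttest_ind(b, a, equal_var=not welch)
        name = "welch_t" if welch else "student_t"
    elif test == "mannwhitney":
        if np.all(a == b[: len(a)]) and np.std(a) == 0 and np.std(b) == 0:
            stat, p = float(len(a) * len(b)) / 2.0, 1.0
        else:
            stat, p = stats.mannwhitneyu(b, a, alternative="two-sided")
        name = "mann_whitney_u"
    else:
        raise ValueError(f"unknown test {test!r}")
    return ComparisonResult(name, float(stat), float(p), mean_c, mean_t, fold, percent)


@dataclass(frozen=True)
class AnovaTukeyResult:
    f_statistic: float
    p_value: float
    pairwise: dict[tuple[str, str], float]  # Tukey HSD adjusted p per group pair


def anova_tukey(groups: dict[str, np.ndarray]) -> AnovaTukeyResult:
    """One-way ANOVA with Tukey HSD (Tukey-Kramer for unbalanced groups)."""
    if len(groups) < 3:
        raise ValueError("need at least 3 groups")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for k, v in arrays.items():
        if len(v) < 2:
            raise ValueError(f"group {k!r} needs n >= 2")
    names = sorted(arrays)
    values = [arrays[k] for k in names]
    if all(np.std(v) == 0 for v in values) and len({float(v.mean()) for v in values}) == 1:
        pairwise = {pair: 1.0 for pair in itertools.combinations(names, 2)}
        return AnovaTukeyResult(0.0, 1.0, pairwise)
    f, p = stats.f_oneway(*values)
    tukey = stats.tukey_hsd(*values)
    pairwise = {}
    for (i, a), (j, b) in itertools.combinations(enumerate(names), 2):
        pairwise[(a, b)] = float(tukey.pvalue[i, j])
    return AnovaTukeyResult(float(f), float(p), pairwise)


def measurements_table(measurements: list[CellMeasurement]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "cell": [m.cell_id for m in measurements],
            "group": [m.group for m in measurements],
            "replicate": [m.replicate for m in measurements],
            "int_den": [m.integrated_density for m in measurements],
            "area": [m.area for m in measurements],
            "bg_mean": [m.background_mean for m in measurements],
            "ctcf": [m.ctcf for m in measurements],
        }
    )


def read_measurements(path) -> list[CellMeasurement]:
    """Measurements from a TSV with columns cell, group, replicate, int_den, area, bg_mean."""
    df = pd.read_csv(path, sep="\t")
    out = []
    for _, row in df.iterrows():
        ctcf = row.get("ctcf")
        if ctcf is None or pd.isna(ctcf):
            ctcf = compute_ctcf(row["int_den"], row["area"], row["bg_mean"])
        out.append(CellMeasurement(str(row["cell"]), float(row["int_den"]),
                                   float(row["area"]), float(row["bg_mean"]),
                                   float(ctcf), str(row["replicate"]), str(row["group"])))
    return out
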