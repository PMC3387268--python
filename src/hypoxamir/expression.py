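"""Phenotype scoring, qPCR quantification, clustering, correlation calls.

Covers the waterlogging tolerance coefficient (WTC = treated trait mean /
control trait mean), stem-loop RT primer construction for mature miRNAs,
2^-ddCt relative quantification against an 18S-style reference, hierarchical
clustering of log2 treatment/control ratios, and the miRNA-target
negative-correlation call (Pearson r < 0 in every inbred line).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .core_io import dna, revcomp

TRAITS = ("RL", "LL", "RW", "LW", "TW")
LINES = ("tolerant", "mid", "sensitive")
TIMES = ("1h", "2h", "4h")

# the fixed selfed stem-loop body of the RT primer
STEMLOOP_CONSTANT = "GTCGTATCCAGTGCAGGGTCCGAGGTATTCGCACTGGATACGAC"


@dataclass
class TraitMeasurement:
    line: str
    condition: str
    trait: str
    values: list[float]

    def __post_init__(self) -> None:
        if len(self.values) < 3:
            raise ValueError("at least 3 replicate values are required")
        if any(v <= 0 for v in self.values):
            raise ValueError("trait values must be positive")

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))


def compute_wtc(treated: TraitMeasurement, control: TraitMeasurement) -> float:
    """Waterlogging tolerance coefficient for one trait."""
    if (treated.line, treated.trait) != (control.line, control.trait):
        raise ValueError("treated and control must share line and trait")
    if control.mean <= 0:
        raise ValueError("control mean must be positive")
    return treated.mean / control.mean


def stemloop_primer(mature_seq: str) -> str:
    """Stem-loop RT primer: constant 44-nt body plus the DNA reverse
    complement of the mature miRNA's last 6 nt."""
    seq = dna(mature_seq)
    if len(seq) < 6:
        raise ValueError("mature sequence must be at least 6 nt")
    return STEMLOOP_CONSTANT + revcomp(seq[-6:])


def relative_expression(
    ct_target_trt: float | list[float],
    ct_ref_trt: float | list[float],
    ct_target_ctl: float | list[float],
    ct_ref_ctl: float | list[float],
) -> float:
    """2^-ddCt with replicate Cts averaged before differencing."""
    mean = lambda x: float(np.mean(x))
    ddct = (mean(ct_target_trt) - mean(ct_ref_trt)) - (
        mean(ct_target_ctl) - mean(ct_ref_ctl)
    )
    return 2.0 ** (-ddct)


def quantify_ct_table(ct_table: pd.DataFrame, reference_id: str = "18S") -> pd.DataFrame:
    """Relative expression per (entity, line, time) from a long Ct table.

    Expected columns: ``entity``, ``line``, ``time``, ``condition``
    (treated/control), ``replicate``, ``ct``.  The reference entity's Cts are
    matched by line, time and condition.
    """
    rows = []
    ref = ct_table[ct_table["entity"] == reference_id]
    targets = ct_table[ct_table["entity"] != reference_id]
    for (entity, line, time), grp in targets.groupby(["entity", "line", "time"]):
        ref_grp = ref[(ref["line"] == line) & (ref["time"] == time)]
        pick = lambda df, cond: list(df.loc[df["condition"] == cond, "ct"])
        rel = relative_expression(
            pick(grp, "treated"),
            pick(ref_grp, "treated"),
            pick(grp, "control"),
            pick(ref_grp, "control"),
        )
        rows.append(
            {
                "entity": entity,
                "line": line,
                "time": time,
                "rel_expr": rel,
                "log2_ratio": math.log2(rel),
            }
        )
    return pd.DataFrame(rows)


def cluster_profiles(
    log2_matrix: pd.DataFrame, k: int = 4
) -> tuple[np.ndarray, pd.Series, list[str]]:
    """Agglomerative clustering (Euclidean, average linkage) of log2 ratios.

    Rows are entities, columns line-by-time conditions.  Returns the linkage
    matrix, per-row cluster labels, and the heatmap-ready leaf order.  Ties
    in the distance matrix are broken deterministically by row index (scipy's
    ordering is stable for equal distances).
    """
    if log2_matrix.isna().any().any():
        r, c = np.argwhere(log2_matrix.isna().to_numpy())[0]
        raise ValueError(
            f"missing value at ({log2_matrix.index[r]}, {log2_matrix.columns[c]})"
        )
    data = log2_matrix.to_numpy(dtype=float)
    link = hierarchy.linkage(pdist(data, metric="euclidean"), method="average")
    labels = hierarchy.fcluster(link, t=k, criterion="maxclust")
    order = hierarchy.leaves_list(link)
    row_order = [log2_matrix.index[i] for i in order]
    return link, pd.Series(labels, index=log2_matrix.index, name="cluster"), row_order


def call_negative_correlation(
    mirna_profile: pd.DataFrame, target_profile: pd.DataFrame
) -> tuple[bool, dict[str, float]]:
    """True iff the target's log2 ratios correlate negatively with the
    miRNA's in every line (Pearson r < 0 over the time course).

    Profiles are DataFrames indexed by line with one column per time point.
    A line with zero variance on either side yields an undefined r (NaN) and
    forces the call to False.
    """
    if list(mirna_profile.index) != list(target_profile.index) or list(
        mirna_profile.columns
    ) != list(target_profile.columns):
        raise ValueError("profiles must share the line x time design")
    per_line: dict[str, float] = {}
    call = True
    for line in mirna_profile.index:
        x = mirna_profile.loc[line].to_numpy(dtype=float)
        y = target_profile.loc[line].to_numpy(dtype=float)
        if np.std(x) == 0 or np.std(y) == 0:
            per_line[line] = math.nan
            call = False
            continue
        r = float(np.corrcoef(x, y)[0, 1])
        per_line[line] = r
        if not r < 0:
            call = False
    return call, per_line


def two_sample_ttest(a: list[float], b: list[float]) -> tuple[float, float]:
    """Plain Welch two-sample t-test helper (not a contribution)."""
    from scipy import stats

    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.pvalue)
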