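"""TPM normalization, pooled-library exact DE testing and intersection sets.

Counts are normalized to transcripts per million per library, records whose
TPM never reaches the expression floor (default 30) are excluded, and each
heat timepoint is tested against the 0 h control with an exact conditional
binomial test on the pooled counts (Fisher's exact test on the 2x2 table is
available as an alternative).  DE status: up iff log2 ratio >= 1 and
p < 0.05; down iff log2 ratio <= -1 and p < 0.05; ns otherwise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from itertools import product
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from sirnakit.utils import COMPARISONS, LIBRARIES

DEFAULT_ALPHA = 0.05
DEFAULT_LFC = 1.0
DEFAULT_PSEUDOCOUNT = 0.01
DEFAULT_FLOOR = 30.0


def tpm_normalize(raw_counts: np.ndarray, library_sizes: np.ndarray) -> np.ndarray:
    """tpm[i, j] = raw[i, j] / library_size[j] * 1e6."""
    raw_counts = np.asarray(raw_counts, dtype=float)
    library_sizes = np.asarray(library_sizes, dtype=float)
    if np.any(library_sizes <= 0):
        raise ValueError("library sizes must be positive")
    return raw_counts / library_sizes[None, :] * 1e6


def expression_floor(tpm: np.ndarray, min_tpm: float = DEFAULT_FLOOR) -> np.ndarray:
    """Boolean keep-mask: max TPM across libraries >= min_tpm (inclusive)."""
    tpm = np.asarray(tpm, dtype=float)
    if tpm.size == 0:
        return np.zeros(tpm.shape[0], dtype=bool)
    return tpm.max(axis=1) >= min_tpm


def de_test_binomial(
    count_treatment: int,
    count_control: int,
    size_treatment: float,
    size_control: float,
) -> float:
    """Exact conditional binomial test for two pooled libraries.

    Conditional on k = k_t + k_c, under the null k_t ~ Binomial(k, p0) with
    p0 = size_t / (size_t + size_c).  Two-sided p-value sums the
    probabilities of all outcomes no more likely than the observed one.
    """
    if count_treatment < 0 or count_control < 0:
        raise ValueError("counts must be non-negative")
    if size_treatment <= 0 or size_control <= 0:
        raise ValueError("library sizes must be positive")
    k = count_treatment + count_control
    if k == 0:
        return 1.0
    p0 = size_treatment / (size_treatment + size_control)
    xs = np.arange(k + 1)
    logpmf = stats.binom.logpmf(xs, k, p0)
    # relative tolerance guards float noise at ties (e.g. the modal outcome)
    threshold = logpmf[count_treatment] + 1e-9
    return float(min(1.0, np.exp(logpmf[logpmf <= threshold]).sum()))


def de_test_fisher(
    count_treatment: int,
    count_control: int,
    size_treatment: float,
    size_control: float,
) -> float:
    """Fisher's exact test on [[k_t, size_t - k_t], [k_c, size_c - k_c]]."""
    if count_treatment == 0 and count_control == 0:
        return 1.0
    table = [
        [count_treatment, int(round(size_treatment)) - count_treatment],
        [count_control, int(round(size_control)) - count_control],
    ]
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


def log2_ratio(tpm_treatment: float, tpm_control: float,
               pseudocount: float = DEFAULT_PSEUDOCOUNT) -> float:
    return float(np.log2((tpm_treatment + pseudocount) / (tpm_control + pseudocount)))


def call_status(l2r: float, p: float, alpha: float = DEFAULT_ALPHA,
                lfc: float = DEFAULT_LFC) -> str:
    if p < alpha and l2r >= lfc:
        return "up"
    if p < alpha and l2r <= -lfc:
        return "down"
    return "ns"


def differential_expression(
    sirna_ids: list[str],
    raw_counts: np.ndarray,
    library_sizes: np.ndarray,
    test: str = "binomial",
    alpha: float = DEFAULT_ALPHA,
    lfc: float = DEFAULT_LFC,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    floor: float = DEFAULT_FLOOR,
    bh_adjust: bool = False,
) -> pd.DataFrame:
    """Full DE table: TPM, floor filter, per-comparison test/ratio/status.

    ``raw_counts`` is n x 4 (0/1/6/12 h); comparisons are each heat
    timepoint vs the 0 h control.  With ``bh_adjust`` the p-values are
    Benjamini-Hochberg adjusted per comparison before status calling
    (off by default).
    """
    raw_counts = np.asarray(raw_counts)
    test_fn = {"binomial": de_test_binomial, "fisher": de_test_fisher}[test]
    tpm = tpm_normalize(raw_counts, library_sizes)
    keep = expression_floor(tpm, floor)

    rows: dict[str, list] = {"sirna_id": [s for s, k in zip(sirna_ids, keep) if k]}
    kept_idx = np.flatnonzero(keep)
    for j, lib in enumerate(LIBRARIES):
        rows[f"count_{lib}"] = raw_counts[kept_idx, j].tolist()
        rows[f"tpm_{lib}"] = tpm[kept_idx, j].tolist()

    control_j = LIBRARIES.index("0h")
    for comp in COMPARISONS:
        j = LIBRARIES.index(comp)
        l2rs, pvals = [], []
        for i in kept_idx:
            l2rs.append(log2_ratio(tpm[i, j], tpm[i, control_j], pseudocount))
            pvals.append(
                test_fn(int(raw_counts[i, j]), int(raw_counts[i, control_j]),
                        float(library_sizes[j]), float(library_sizes[control_j]))
            )
        pvals = np.asarray(pvals)
        effective = benjamini_hochberg(pvals) if bh_adjust and len(pvals) else pvals
        rows[f"log2_ratio_{comp}"] = l2rs
        rows[f"p_{comp}"] = pvals.tolist()
        rows[f"status_{comp}"] = [
            call_status(l, p, alpha, lfc) for l, p in zip(l2rs, effective)
        ]
    return pd.DataFrame(rows)


def benjamini_hochberg(pvalues: np.ndarray) -> np.ndarray:
    """BH step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(n)
    running = 1.0
    for rank_from_top in range(n - 1, -1, -1):
        i = order[rank_from_top]
        running = min(running, p[i] * n / (rank_from_top + 1))
        adj[i] = running
    return np.minimum(adj, 1.0)


@dataclass
class IntersectionReport:
    """Exclusive Venn regions of the three per-timepoint DE id sets."""

    regions: dict[str, int]  # keys '100','010','001','110','101','011','111'
    totals: dict[str, int]  # per comparison set sizes

    @property
    def common(self) -> int:
        return self.regions["111"]

    @property
    def union(self) -> int:
        return sum(self.regions.values())


def set_intersections(de_ids: dict[str, set[str]]) -> IntersectionReport:
    """Exclusive 3-set region sizes for the (1h, 6h, 12h) DE id sets."""
    sets = [de_ids[c] for c in COMPARISONS]
    regions = {"".join(bits): 0 for bits in product("10", repeat=3)
               if bits != ("0", "0", "0")}
    for elem in set().union(*sets):
        sig = "".join("1" if elem in s else "0" for s in sets)
        regions[sig] += 1
    totals = {c: len(de_ids[c]) for c in COMPARISONS}
    return IntersectionReport(regions, totals)


def intersection_reports(de_table: pd.DataFrame) -> dict[str, IntersectionReport]:
    """Intersection structure for all/up/down DE directions."""
    out = {}
    for direction in ("all", "up", "down"):
        ids = {}
        for comp in COMPARISONS:
            col = de_table[f"status_{comp}"]
            if direction == "all":
                mask = col != "ns"
            else:
                mask = col == direction
            ids[comp] = set(de_table.loc[mask, "sirna_id"])
        out[direction] = set_intersections(ids)
    return out


def write_intersections_json(reports: dict[str, IntersectionReport], path: Path) -> None:
    payload = {
        d: {"regions": r.regions, "totals": r.totals, "common": r.common}
        for d, r in reports.items()
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def common_de_ids(de_table: pd.DataFrame) -> set[str]:
    """siRNAs called DE (either direction) at all three heat timepoints."""
    common: set[str] | None = None
    for comp in COMPARISONS:
        ids = set(de_table.loc[de_table[f"status_{comp}"] != "ns", "sirna_id"])
        common = ids if common is None else common & ids
    return common or set()
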