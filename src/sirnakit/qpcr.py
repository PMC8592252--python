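"""2^-ddCT relative quantification and agreement with sequencing fold changes."""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import stats

from sirnakit.utils import LIBRARIES

CONTROL_TIMEPOINT = "0h"


@dataclass
class CtRecord:
    sirna_id: str
    timepoint: str  # one of 0h/1h/6h/12h
    replicate: int
    ct_target: float
    ct_reference: float

    def __post_init__(self) -> None:
        for v in (self.ct_target, self.ct_reference):
            if not 0 < v < 45:
                raise ValueError(f"Ct value out of range (0, 45): {v}")
        if self.timepoint not in LIBRARIES:
            raise ValueError(f"unknown timepoint: {self.timepoint}")


def read_ct_csv(path: Path) -> list[CtRecord]:
    records = []
    with open(path) as fh:
        for row in csv.DictReader(fh):
            records.append(
                CtRecord(
                    sirna_id=row["sirna_id"],
                    timepoint=str(row["timepoint"]),
                    replicate=int(row["replicate"]),
                    ct_target=float(row["ct_target"]),
                    ct_reference=float(row["ct_reference"]),
                )
            )
    return records


def delta_delta_ct(records: list[CtRecord]) -> dict[str, dict[str, float]]:
    """Per-siRNA relative expression 2^-ddCT against the 0 h control.

    Replicates are averaged on the Ct scale before dCT = mean(ct_target) -
    mean(ct_reference); ddCT(t) = dCT(t) - dCT(0h).  The control timepoint
    yields exactly 1.0 by construction.
    """
    by_sirna: dict[str, dict[str, list[CtRecord]]] = {}
    for r in records:
        by_sirna.setdefault(r.sirna_id, {}).setdefault(r.timepoint, []).append(r)

    out: dict[str, dict[str, float]] = {}
    for sirna_id, by_tp in by_sirna.items():
        if CONTROL_TIMEPOINT not in by_tp:
            raise ValueError(f"{sirna_id}: missing control timepoint")
        dct = {}
        for tp, recs in by_tp.items():
            mean_t = sum(r.ct_target for r in recs) / len(recs)
            mean_ref = sum(r.ct_reference for r in recs) / len(recs)
            dct[tp] = mean_t - mean_ref
        out[sirna_id] = {
            tp: float(2.0 ** -(dct[tp] - dct[CONTROL_TIMEPOINT])) for tp in dct
        }
    return out


def agreement(
    seq_log2fc: np.ndarray, qpcr_log2fc: np.ndarray
) -> tuple[float, float, float]:
    """OLS of sequencing log2FC on qPCR log2FC: (slope, intercept, r^2)."""
    x = np.asarray(qpcr_log2fc, dtype=float)
    y = np.asarray(seq_log2fc, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in input vector")
    fit = stats.linregress(x, y)
    return float(fit.slope), float(fit.intercept), float(fit.rvalue ** 2)


def write_relative_expression_tsv(
    rel: dict[str, dict[str, float]], path: Path
) -> None:
    with open(path, "w") as fh:
        fh.write("sirna_id\t" + "\t".join(f"rel_{tp}" for tp in LIBRARIES) + "\n")
        for sirna_id in sorted(rel):
            vals = [rel[sirna_id].get(tp, float("nan")) for tp in LIBRARIES]
            fh.write(sirna_id + "\t" + "\t".join(f"{v:.6f}" for v in vals) + "\n")


def write_agreement_json(slope: float, intercept: float, r2: float, n: int,
                         path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(
            {"slope": slope, "intercept": intercept, "r_squared": r2, "n_pairs": n},
            fh, indent=2,
        )
        fh.write("\n")
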