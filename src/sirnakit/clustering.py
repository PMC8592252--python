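"""Fuzzy c-means clustering of temporal log2-ratio profiles (Mfuzz-style).

Profiles (one log2 ratio per heat timepoint) are row-standardized and soft
partitioned into c clusters with fuzzifier m.  Centers are initialized from
seeded draws of distinct data rows; several restarts are run and the model
with the lowest objective is kept.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass
class ClusterModel:
    n_clusters: int
    fuzzifier: float
    centers: np.ndarray  # c x T
    memberships: np.ndarray  # n x c, rows sum to 1
    labels: np.ndarray  # argmax membership, ties -> lowest index
    objective: float
    objective_history: list[float]
    n_iter: int


def standardize_profiles(
    profiles: np.ndarray, ids: list[str] | None = None
) -> tuple[np.ndarray, list[int]]:
    """Row z-scoring with population standard deviation.

    Zero-variance rows are excluded; returns (standardized rows, indices of
    the rows that were kept).  Raises if every row is constant.
    """
    X = np.asarray(profiles, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("profiles must be n x T with T >= 2")
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)  # population sigma
    keep = np.flatnonzero(sd[:, 0] > 0)
    if keep.size == 0:
        raise ValueError("all profiles have zero variance")
    Z = (X[keep] - mu[keep]) / sd[keep]
    return Z, keep.tolist()


def _memberships(X: np.ndarray, centers: np.ndarray, m: float) -> np.ndarray:
    # u_ik = 1 / sum_j (d_ik / d_jk)^(2/(m-1)); exact-zero distance -> hard 1
    d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    u = np.zeros_like(d2)
    zero_rows = d2.min(axis=1) == 0.0
    if zero_rows.any():
        for i in np.flatnonzero(zero_rows):
            j = int(np.argmin(d2[i]))
            u[i, j] = 1.0
    ok = ~zero_rows
    if ok.any():
        power = d2[ok] ** (-1.0 / (m - 1.0))
        u[ok] = power / power.sum(axis=1, keepdims=True)
    return u


def _objective(X: np.ndarray, centers: np.ndarray, u: np.ndarray, m: float) -> float:
    d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    return float(((u ** m) * d2).sum())


def fuzzy_cmeans(
    X: np.ndarray,
    c: int = 4,
    m: float = 2.0,
    max_iter: int = 300,
    tol: float = 1e-6,
    seed: int = 0,
    restarts: int = 5,
) -> ClusterModel:
    """Standard fuzzy c-means alternation; best of ``restarts`` seeded runs."""
    X = np.asarray(X, dtype=float)
    if c < 2:
        raise ValueError("c must be >= 2")
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite input")
    n = X.shape[0]
    if n < c:
        raise ValueError("need at least c rows")
    if m <= 1.0:
        raise ValueError("fuzzifier m must be > 1")

    rng = np.random.default_rng(seed)
    best: ClusterModel | None = None
    for _ in range(restarts):
        centers = X[rng.choice(n, size=c, replace=False)].copy()
        history: list[float] = []
        for it in range(1, max_iter + 1):
            u = _memberships(X, centers, m)
            um = u ** m
            new_centers = (um.T @ X) / um.sum(axis=0)[:, None]
            history.append(_objective(X, new_centers, u, m))
            movement = float(np.abs(new_centers - centers).max())
            centers = new_centers
            if movement < tol:
                break
        u = _memberships(X, centers, m)
        model = ClusterModel(
            n_clusters=c,
            fuzzifier=m,
            centers=centers,
            memberships=u,
            labels=u.argmax(axis=1),
            objective=_objective(X, centers, u, m),
            objective_history=history,
            n_iter=len(history),
        )
        if best is None or model.objective < best.objective:
            best = model
    assert best is not None
    return best


def cluster_summary(model: ClusterModel, profiles: np.ndarray) -> pd.DataFrame:
    """Per-cluster size, mean standardized trajectory and trend descriptor."""
    X = np.asarray(profiles, dtype=float)
    rows = []
    for k in range(model.n_clusters):
        members = np.flatnonzero(model.labels == k)
        if members.size == 0:
            rows.append({"cluster": k, "size": 0, "mean_trajectory": "",
                         "trend": "undefined"})
            continue
        mean_traj = X[members].mean(axis=0)
        steps = np.diff(mean_traj)
        trend = ",".join("up" if s > 0 else ("down" if s < 0 else "flat")
                         for s in steps)
        rows.append({
            "cluster": k,
            "size": int(members.size),
            "mean_trajectory": ";".join(f"{v:.4f}" for v in mean_traj),
            "trend": trend,
        })
    return pd.DataFrame(rows)


def write_memberships_tsv(model: ClusterModel, ids: list[str], path: Path) -> None:
    df = pd.DataFrame(
        model.memberships, columns=[f"cluster_{k}" for k in range(model.n_clusters)]
    )
    df.insert(0, "sirna_id", ids)
    df["label"] = model.labels
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")
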