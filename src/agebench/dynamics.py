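"""Dynamic-systems view of model evolution.

A model retrained on a sliding window traces a trajectory through its
feature-importance space.  Projected onto the first two principal components
this becomes a *phase portrait*: clusters are quasi-stable states the model
is attracted to, transitions are regime changes.  Independently, the raw
(dT, E_rel) cloud of a degradation suite can develop dense basins of highly
probable errors — detected here as modes of a 2-D kernel density estimate.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.segmentation import watershed
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .engine import AgingResult
from .models import HyperparamSet, ModelFamily, compute_importance, fit_regressor
from .timeline import TimestampedDataset, TimeWindow, slice_window

__all__ = [
    "ImportanceTrajectory",
    "PhasePath",
    "AttractorReport",
    "TrajectoryTooShortError",
    "importance_trajectory",
    "project_phase_portrait",
    "cluster_states",
    "find_error_attractors",
]


class TrajectoryTooShortError(ValueError):
    """Fewer than 3 usable sliding windows."""


@dataclasses.dataclass
class ImportanceTrajectory:
    """Per-window normalized feature-importance vectors, ordered in time."""

    window_centers: np.ndarray
    window_days: float
    step_days: float
    matrix: np.ndarray  # n_windows x n_features, unit L2 rows (where nonzero)
    feature_names: list[str]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.matrix, columns=self.feature_names)
        df.insert(0, "window_center", self.window_centers)
        return df


@dataclasses.dataclass
class PhasePath:
    """2-D principal-component projection of an importance trajectory."""

    coordinates: np.ndarray  # n_windows x 2 (PC1, PC2 scores)
    explained_variance_fractions: tuple[float, float]
    loadings: np.ndarray  # 2 x n_features
    feature_names: list[str]
    window_centers: np.ndarray
    step_days: float
    state_labels: np.ndarray | None = None
    dwell_times: dict[int, float] | None = None
    n_transitions: int | None = None
    rank_deficient: bool = False

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "window_center": self.window_centers,
                "pc1": self.coordinates[:, 0],
                "pc2": self.coordinates[:, 1],
            }
        )
        if self.state_labels is not None:
            df["state"] = self.state_labels
        return df


@dataclasses.dataclass
class AttractorReport:
    """Density modes ("error basins") of the (dT, E_rel) cloud."""

    modes: list[dict]  # each: dT_center, e_rel_center, density, mass_fraction
    bandwidths: tuple[float, float]
    unassigned_mass: float

    def to_dict(self) -> dict:
        return {
            "modes": self.modes,
            "bandwidths": list(self.bandwidths),
            "unassigned_mass": self.unassigned_mass,
        }


def importance_trajectory(
    ds: TimestampedDataset,
    family: str | ModelFamily,
    hyperparams: HyperparamSet | dict,
    window_days: float = 90.0,
    step_days: float = 30.0,
    min_records: int = 50,
    seed: int = 0,
) -> ImportanceTrajectory:
    """Refit the model on each sliding window and record its importance vector.

    Windows advance by ``step_days`` over the dataset span; each fit uses only
    that window's records, and importance is evaluated on the same window.
    Windows under ``min_records`` records are skipped with a warning.
    """
    code = family.code if isinstance(family, ModelFamily) else family
    span = ds.span
    if span < 2 * window_days:
        raise TrajectoryTooShortError(
            f"span {span:.0f} d supports no sliding trajectory with {window_days:.0f} d windows"
        )
    start0 = float(ds.timestamps[0])
    starts = np.arange(start0, start0 + span - window_days + 1e-9, step_days)

    centers, rows = [], []
    for i, s in enumerate(starts):
        w = TimeWindow(s, s + window_days)
        if ds.window_record_count(w) < min_records:
            warnings.warn(f"window [{w.start:.0f}, {w.end:.0f}) under {min_records} records; skipped")
            continue
        sub = slice_window(ds, w)
        model = fit_regressor(code, hyperparams, sub, seed=(seed ^ i) & 0x7FFFFFFF)
        rows.append(compute_importance(model, sub, seed=(seed ^ i) & 0x7FFFFFFF))
        centers.append(s + window_days / 2.0)
    if len(rows) < 3:
        raise TrajectoryTooShortError(f"only {len(rows)} usable windows; need >= 3")
    return ImportanceTrajectory(
        window_centers=np.array(centers),
        window_days=float(window_days),
        step_days=float(step_days),
        matrix=np.vstack(rows),
        feature_names=list(ds.feature_names),
    )


def project_phase_portrait(traj: ImportanceTrajectory) -> PhasePath:
    """PCA (via SVD) of the column-centered importance matrix, first two components.

    Sign convention: each loading vector's largest-magnitude entry is positive.
    A rank-deficient matrix gets its second component zeroed and is flagged.
    """
    if traj.matrix.shape[0] < 3:
        raise TrajectoryTooShortError("need >= 3 windows for a phase portrait")
    if traj.matrix.shape[1] < 2:
        raise ValueError("need >= 2 features")
    M = traj.matrix - traj.matrix.mean(axis=0)
    U, s, Vt = np.linalg.svd(M, full_matrices=False)
    total = float(np.sum(s**2))

    n_feat = traj.matrix.shape[1]
    coords = np.zeros((M.shape[0], 2))
    loadings = np.zeros((2, n_feat))
    fracs = [0.0, 0.0]
    rank = int(np.sum(s > 1e-12 * max(1.0, s[0] if len(s) else 1.0)))
    for c in range(min(2, len(s))):
        if s[c] <= 1e-12:
            continue
        load = Vt[c]
        score = U[:, c] * s[c]
        if load[np.argmax(np.abs(load))] < 0:  # sign convention
            load, score = -load, -score
        loadings[c] = load
        coords[:, c] = score
        fracs[c] = float(s[c] ** 2 / total) if total > 0 else 0.0
    return PhasePath(
        coordinates=coords,
        explained_variance_fractions=(fracs[0], fracs[1]),
        loadings=loadings,
        feature_names=list(traj.feature_names),
        window_centers=traj.window_centers.copy(),
        step_days=traj.step_days,
        rank_deficient=rank < 2,
    )


def cluster_states(path: PhasePath, k: int | str = "auto", seed: int = 0) -> PhasePath:
    """Centroid-based clustering of the phase-path coordinates.

    ``k="auto"`` selects k in 2..6 by silhouette score (10 seeded restarts
    per k).  Degenerate all-identical coordinates force a single cluster.
    Fills ``state_labels``, per-cluster ``dwell_times`` (step_days per
    assigned window) and the transition count.
    """
    X = path.coordinates
    n = X.shape[0]
    if n < 4:
        raise ValueError("need >= 4 windows to cluster states")

    if np.allclose(X, X[0]):
        labels = np.zeros(n, dtype=int)
    elif k == "auto":
        best_labels, best_score = None, -np.inf
        for kk in range(2, min(6, n - 1) + 1):
            km = KMeans(n_clusters=kk, n_init=10, random_state=seed).fit(X)
            if len(np.unique(km.labels_)) < 2:
                continue
            score = silhouette_score(X, km.labels_)
            if score > best_score:
                best_score, best_labels = score, km.labels_
        labels = best_labels if best_labels is not None else np.zeros(n, dtype=int)
    else:
        km = KMeans(n_clusters=int(k), n_init=10, random_state=seed).fit(X)
        labels = km.labels_

    path.state_labels = np.asarray(labels, dtype=int)
    path.dwell_times = {
        int(c): float(np.sum(labels == c) * path.step_days) for c in np.unique(labels)
    }
    path.n_transitions = int(np.sum(labels[1:] != labels[:-1]))
    return path


def _silverman_bandwidth(x: np.ndarray) -> float:
    # per-axis Silverman factor for a 2-D product kernel
    return float(np.std(x) * len(x) ** (-1.0 / 6.0))


def find_error_attractors(
    results,
    grid_size: int = 80,
    bandwidths: tuple[float, float] | None = None,
    density_ratio: float = 2.0,
) -> AttractorReport:
    """Detect dense basins of probable (dT, E_rel) outcomes.

    The E_rel axis is log-transformed (errors span decades in explosive
    cases) before a product-Gaussian kernel density estimate with per-axis
    Silverman bandwidths.  Modes are grid local maxima with density at least
    ``density_ratio`` × the median grid density; each mode's mass fraction is
    the integral of density over its watershed basin, normalized so all basin
    masses plus the unassigned mass sum to 1.  Reported E_rel centers are
    back-transformed to the original scale.
    """
    if isinstance(results, AgingResult):
        dt, e_rel = results.dT, results.e_rel
    else:
        dt, e_rel = (np.asarray(a, dtype=float) for a in results)
    x = dt
    y = np.log(e_rel)
    n = len(x)

    hx = bandwidths[0] if bandwidths else _silverman_bandwidth(x)
    hy = bandwidths[1] if bandwidths else _silverman_bandwidth(y)
    hx = max(hx, 1e-9)
    hy = max(hy, 1e-9)

    gx = np.linspace(x.min() - hx, x.max() + hx, grid_size)
    gy = np.linspace(y.min() - hy, y.max() + hy, grid_size)
    # product Gaussian kernel evaluated on the grid, chunked over data
    dens = np.zeros((grid_size, grid_size))
    chunk = 2000
    for i in range(0, n, chunk):
        dx = (gx[:, None] - x[None, i : i + chunk]) / hx
        dy = (gy[:, None] - y[None, i : i + chunk]) / hy
        kx = np.exp(-0.5 * dx**2)
        ky = np.exp(-0.5 * dy**2)
        dens += kx @ ky.T
    dens /= n * 2 * np.pi * hx * hy

    local_max = (ndimage.maximum_filter(dens, size=3, mode="nearest") == dens) & (dens > 0)
    peak_idx = np.argwhere(local_max)
    markers = np.zeros_like(dens, dtype=int)
    for m, (i, j) in enumerate(peak_idx, start=1):
        markers[i, j] = m
    basins = watershed(-dens, markers=markers)

    cell = (gx[1] - gx[0]) * (gy[1] - gy[0])
    total_mass = float(dens.sum() * cell)
    median_density = float(np.median(dens))

    modes = []
    assigned = 0.0
    for m, (i, j) in enumerate(peak_idx, start=1):
        d = float(dens[i, j])
        if d < density_ratio * median_density:
            continue
        mass = float(dens[basins == m].sum() * cell) / total_mass
        assigned += mass
        modes.append(
            {
                "dT_center": float(gx[i]),
                "e_rel_center": float(np.exp(gy[j])),
                "density": d,
                "mass_fraction": mass,
            }
        )
    modes.sort(key=lambda mo: -mo["density"])
    return AttractorReport(
        modes=modes,
        bandwidths=(hx, hy),
        unassigned_mass=max(0.0, 1.0 - assigned),
    )
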