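"""Ordered conformational states from an ensemble: PCA + Gaussian mixtures.

Conformers are rigid-body superposed onto the first frame, PCA is applied
to the flattened coordinates, and a Gaussian mixture model is fitted to
the leading principal components (six by default).  The number of states
K is chosen by the Bayesian information criterion among candidate k whose
smallest cluster still holds a minimum occupancy.  States are then
relabelled 1..K in order of increasing mean PC1, so the label axis tracks
the conformational transition, and each state is represented by the
member nearest to its cluster mean ("cluster centre").
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.decomposition import PCA
from sklearn.mixture import GaussianMixture

from .bead_model import BeadModel, Ensemble

__all__ = [
    "StateModel",
    "superpose",
    "superpose_ensemble",
    "fit_pca",
    "project",
    "cluster_gmm",
    "fit_state_model",
    "state_rmsd_stats",
    "save_state_model",
    "load_state_model",
]


@dataclass
class StateModel:
    """PCA basis plus mixture clustering of an ensemble.

    ``labels`` are 1-based and ordered so that the per-state mean PC1
    (``order_key``) is non-decreasing with the label.  ``centers[k-1]`` is
    the conformer index representing state k.
    """

    pca_mean: np.ndarray
    pca_components: np.ndarray  # (n_pc, n_features)
    n_pc: int
    explained_variance: np.ndarray | None = None
    labels: np.ndarray | None = None
    centers: np.ndarray | None = None
    K: int = 0
    order_key: np.ndarray | None = None
    bic_table: dict = field(default_factory=dict)

    def validate(self):
        if self.labels is not None:
            if self.labels.min() < 1 or self.labels.max() > self.K:
                raise ValueError("labels must lie in 1..K")
            for k in range(1, self.K + 1):
                if self.labels[self.centers[k - 1]] != k:
                    raise ValueError(f"center of state {k} is not a member of it")
            if np.any(np.diff(self.order_key) < 0):
                raise ValueError("states must be ordered by mean PC1")


def superpose(a: BeadModel, b: BeadModel):
    """Least-squares rigid superposition of ``b`` onto ``a`` (Kabsch).

    Returns ``(rotation, translation, rmsd)`` such that
    ``b.centers @ rotation.T + translation`` best fits ``a.centers``;
    rmsd is in nm after superposition.
    """
    if len(a) != len(b):
        raise ValueError("bead counts differ")
    pa, pb = a.centers, b.centers
    ca, cb = pa.mean(axis=0), pb.mean(axis=0)
    qa, qb = pa - ca, pb - cb
    if len(a) < 3 or np.linalg.matrix_rank(qa, tol=1e-12) < 2:
        raise ValueError("need at least 3 non-collinear beads for superposition")
    h = qb.T @ qa
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = ca - rot @ cb
    resid = qa - qb @ rot.T
    rmsd = float(np.sqrt((resid ** 2).sum(axis=1).mean()))
    return rot, trans, rmsd


def _apply_superposition(model: BeadModel, rot, trans) -> BeadModel:
    return BeadModel(model.centers @ rot.T + trans, model.radii, model.kinds, model.name)


def superpose_ensemble(ens: Ensemble, ref_index: int = 0) -> Ensemble:
    """Superpose every conformer onto the reference frame (default first),
    removing rigid-body motion before state definition."""
    ref = ens.conformers[ref_index]
    aligned = []
    for m in ens.conformers:
        rot, trans, _ = superpose(ref, m)
        aligned.append(_apply_superposition(m, rot, trans))
    return Ensemble(aligned, frame_ids=list(ens.frame_ids))


def fit_pca(ens: Ensemble, n_pc: int = 6, *, align: bool = True) -> StateModel:
    """Fit the PCA basis (first ``n_pc`` components) to an ensemble.

    Conformers are superposed onto the first frame unless ``align=False``.
    Rank-deficient ensembles yield fewer components, with a warning.
    """
    if len(ens) < n_pc + 1:
        raise ValueError(f"need at least {n_pc + 1} conformers for {n_pc} components")
    work = superpose_ensemble(ens) if align else ens
    x = work.coordinates().reshape(len(work), -1)
    n_keep = min(n_pc, np.linalg.matrix_rank(x - x.mean(axis=0), tol=1e-10))
    if n_keep < n_pc:
        import warnings

        warnings.warn(f"rank-deficient ensemble: keeping {n_keep} of {n_pc} components")
    pca = PCA(n_components=n_keep, svd_solver="full")
    pca.fit(x)
    return StateModel(
        pca_mean=pca.mean_,
        pca_components=pca.components_,
        n_pc=n_keep,
        explained_variance=pca.explained_variance_,
    )


def project(sm: StateModel, ens: Ensemble, *, align: bool = True) -> np.ndarray:
    """Project an ensemble onto the state model's PCA basis; (n, n_pc)."""
    work = superpose_ensemble(ens) if align else ens
    x = work.coordinates().reshape(len(work), -1)
    return (x - sm.pca_mean) @ sm.pca_components.T


def cluster_gmm(sm: StateModel, proj: np.ndarray, *, k_range=range(2, 31),
                min_occupancy: float | int = 0.01, n_init: int = 5,
                seed: int = 0) -> StateModel:
    """Complete a state model by Gaussian-mixture clustering of the PCA
    projections.

    K minimises the BIC over ``k_range``, restricted to k whose smallest
    cluster holds at least ``min_occupancy`` points (a fraction of n if
    < 1, else an absolute count).  Full covariances, ``n_init`` restarts,
    deterministic under ``seed``.
    """
    n = len(proj)
    k_range = [k for k in k_range if k < n]
    if not k_range:
        raise ValueError("k_range contains no k smaller than the sample size")
    min_count = int(np.ceil(min_occupancy * n)) if min_occupancy < 1 else int(min_occupancy)

    bic_table = {}
    best = None
    for k in k_range:
        gmm = GaussianMixture(n_components=k, covariance_type="full",
                              n_init=n_init, random_state=seed)
        raw = gmm.fit_predict(proj)
        bic = float(gmm.bic(proj))
        occ_ok = np.bincount(raw, minlength=k).min() >= min_count
        bic_table[k] = {"bic": bic, "admissible": bool(occ_ok)}
        if occ_ok and (best is None or bic < best[0]):
            best = (bic, k, raw)
    if best is None:
        raise ValueError(f"no admissible cluster count; BIC table: {bic_table}")
    _, K, raw = best

    # order states by increasing mean PC1; relabelling preserves the partition
    mean_pc1 = np.array([proj[raw == c, 0].mean() for c in range(K)])
    order = np.argsort(mean_pc1, kind="stable")
    relabel = np.empty(K, dtype=int)
    relabel[order] = np.arange(1, K + 1)
    labels = relabel[raw]

    centers = np.empty(K, dtype=int)
    for k in range(1, K + 1):
        (members,) = np.nonzero(labels == k)
        mean = proj[members].mean(axis=0)
        centers[k - 1] = members[np.argmin(((proj[members] - mean) ** 2).sum(axis=1))]

    out = StateModel(
        pca_mean=sm.pca_mean,
        pca_components=sm.pca_components,
        n_pc=sm.n_pc,
        explained_variance=sm.explained_variance,
        labels=labels,
        centers=centers,
        K=K,
        order_key=np.sort(mean_pc1),
        bic_table=bic_table,
    )
    out.validate()
    return out


def fit_state_model(ens: Ensemble, n_pc: int = 6, *, k_range=range(2, 31),
                    min_occupancy: float | int = 0.01, seed: int = 0) -> StateModel:
    """Convenience: superpose, fit PCA, project and cluster in one call."""
    sm = fit_pca(ens, n_pc=n_pc)
    proj = project(sm, ens)
    return cluster_gmm(sm, proj, k_range=k_range, min_occupancy=min_occupancy,
                       seed=seed)


def state_rmsd_stats(ens: Ensemble, sm: StateModel, *, max_pairs_members: int = 200,
                     seed: int = 0):
    """Within-state and adjacent-state RMSD statistics (nm).

    Returns ``(within, between)``: per-state mean pairwise superposed RMSD
    (states with > ``max_pairs_members`` members use a seeded subsample),
    and the centre-to-centre RMSD of each adjacent state pair (k, k+1).
    """
    if sm.labels is None:
        raise ValueError("state model is not clustered")
    rng = np.random.default_rng(seed)
    within = np.zeros(sm.K)
    for k in range(1, sm.K + 1):
        (members,) = np.nonzero(sm.labels == k)
        if len(members) > max_pairs_members:
            members = rng.choice(members, size=max_pairs_members, replace=False)
        if len(members) < 2:
            within[k - 1] = 0.0
            continue
        vals = []
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                _, _, r = superpose(ens[members[i]], ens[members[j]])
                vals.append(r)
        within[k - 1] = float(np.mean(vals))
    between = np.array([
        superpose(ens[sm.centers[k]], ens[sm.centers[k + 1]])[2]
        for k in range(sm.K - 1)
    ])
    return within, between


def save_state_model(path, sm: StateModel) -> None:
    """Persist a state model as a directory: JSON metadata + npz arrays."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    meta = {
        "n_pc": int(sm.n_pc),
        "K": int(sm.K),
        "clustered": sm.labels is not None,
    }
    (path / "state_model.json").write_text(json.dumps(meta, indent=2))
    arrays = {
        "pca_mean": sm.pca_mean,
        "pca_components": sm.pca_components,
    }
    if sm.explained_variance is not None:
        arrays["explained_variance"] = sm.explained_variance
    if sm.labels is not None:
        arrays.update(labels=sm.labels, centers=sm.centers, order_key=sm.order_key)
    np.savez(path / "arrays.npz", **arrays)


def load_state_model(path) -> StateModel:
    path = Path(path)
    meta = json.loads((path / "state_model.json").read_text())
    with np.load(path / "arrays.npz") as data:
        arrays = {k: data[k] for k in data.files}
    return StateModel(
        pca_mean=arrays["pca_mean"],
        pca_components=arrays["pca_components"],
        n_pc=meta["n_pc"],
        explained_variance=arrays.get("explained_variance"),
        labels=arrays.get("labels"),
        centers=arrays.get("centers"),
        K=meta["K"],
        order_key=arrays.get("order_key"),
    )
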