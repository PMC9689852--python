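"""Common spatio-temporal pattern (CSTP) feature extraction.

The method separates two epoch classes by a whitened generalized
eigendecomposition (GED), applied first in the spatial domain (common
spatial patterns, CSP) and then in the temporal domain (common temporal
patterns, CTP):

1.  Per class, average the trace-normalized per-epoch channel covariances
    ``R_c = mean_i X_i X_i^T / trace(X_i X_i^T)`` after removing outlying
    epochs (z-scored Frobenius distance of each epoch's covariance to the
    class mean).
2.  Eigendecompose the composite ``R = R_A + R_B = U0 S U0^T`` and whiten
    with ``P = S^{-1/2} U0^T``; the whitened class covariances share
    eigenvectors ``U`` and their eigenvalues sum to one per direction.
3.  The projection matrix is ``W = U^T P``; its rows are spatial filters,
    the columns of ``pinv(W)`` are the corresponding scalp patterns.  The
    rows belonging to the 4 largest and 4 smallest eigenvalues are kept.
4.  The CTP stage repeats the same GED on time-by-time (T x T) covariances
    of the spatially filtered epochs, downsampled to 100 Hz (T = 101) and
    shrunk toward the scaled identity with coefficient 0.1.  Two temporal
    filter sets are trained per class pair — one on the first four
    (class-A-dominant) virtual channels, one on the last four — and the
    4 largest + 4 smallest eigenvector filters are kept from each set.

With three class pairs (MC vs non-target, MI vs non-target, MI vs MC) this
yields 3 pairs x 2 sets x 8 = 48 temporal filters; projecting each of the
8 virtual channels of a pair onto its 16 temporal filters gives
3 x 8 x 16 = 384 features per epoch.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import linalg
from sklearn.covariance import shrunk_covariance

from .preprocess import EpochSet, downsample_epochs
from .simulate import MC_TARGET, MI_TARGET, NONTARGET

logger = logging.getLogger(__name__)

#: The three class pairs, in fixed order.  Per pair, the *first* spatial
#: filters maximize variance of pair[0] and the *last* ones of pair[1].
DEFAULT_PAIRS = (
    (MC_TARGET, NONTARGET),
    (MI_TARGET, NONTARGET),
    (MI_TARGET, MC_TARGET),
)


def pair_name(pair) -> str:
    return f"{pair[0]}_vs_{pair[1]}"


@dataclass
class CovarianceEstimate:
    """Averaged trace-normalized covariance with its epoch-cleaning report."""

    matrix: np.ndarray
    n_epochs_used: int
    removed: list = field(default_factory=list)


@dataclass
class SpatialFilterBank:
    """CSP result for one class pair.

    ``W`` rows are spatial filters (virtual channel = filter row · channels);
    ``patterns`` columns (pinv of W) are the forward scalp projections.
    """

    pair: tuple
    W: np.ndarray            # n_filters x n_channels (full square)
    eigvals_a: np.ndarray    # descending for class pair[0]
    eigvals_b: np.ndarray
    selected: np.ndarray     # indices of the 4 largest + 4 smallest
    patterns: np.ndarray     # n_channels x n_filters

    @property
    def W_selected(self) -> np.ndarray:
        return self.W[self.selected]

    @property
    def patterns_selected(self) -> np.ndarray:
        return self.patterns[:, self.selected]

    @property
    def n_selected(self) -> int:
        return len(self.selected)


@dataclass
class TemporalFilterSet:
    """One CTP solution: temporal eigenvector filters of length T."""

    subset: str              # 'first' or 'last' spatial-filter subset
    W: np.ndarray            # T x T, rows = temporal filters
    eigvals_a: np.ndarray
    eigvals_b: np.ndarray
    selected: np.ndarray
    patterns: np.ndarray     # T x T, columns = temporal patterns
    shrinkage: float

    @property
    def filters(self) -> np.ndarray:
        return self.W[self.selected]

    @property
    def patterns_selected(self) -> np.ndarray:
        return self.patterns[:, self.selected]


@dataclass
class TemporalFilterBank:
    """The two CTP sets of one class pair (16 selected filters)."""

    pair: tuple
    sets: dict  # 'first'/'last' -> TemporalFilterSet

    @property
    def n_selected(self) -> int:
        return sum(len(s.selected) for s in self.sets.values())

    def stacked_filters(self) -> np.ndarray:
        return np.vstack([self.sets["first"].filters, self.sets["last"].filters])


@dataclass
class CstpModel:
    """Fitted CSTP feature extractor: one spatial + temporal bank per pair."""

    spatial: dict            # pair name -> SpatialFilterBank
    temporal: dict           # pair name -> TemporalFilterBank
    temporal_rate: float = 100.0
    input_rate: float = 250.0          # sampling rate the model was fit on
    feature_mode: str = "projection"   # or 'logvar'

    @property
    def n_temporal_filters(self) -> int:
        return sum(bank.n_selected for bank in self.temporal.values())

    @property
    def n_features(self) -> int:
        return sum(
            self.spatial[name].n_selected * self.temporal[name].n_selected
            for name in self.spatial
        )


# ---------------------------------------------------------------------------
# epoch cleaning and covariance estimation

def _epoch_covariances(data: np.ndarray) -> np.ndarray:
    covs = np.einsum("eit,ejt->eij", data, data)
    traces = np.trace(covs, axis1=1, axis2=2)
    if np.any(traces <= 0):
        raise ValueError("epoch with zero total variance")
    return covs / traces[:, None, None]


def clean_epochs(epochs: EpochSet, z_threshold: float = 2.5, max_iter: int = 3,
                 min_keep: float = 0.8):
    """Drop epochs whose covariance is far from their class mean covariance.

    Distances are Frobenius norms of (per-epoch covariance − class mean),
    z-scored within class; epochs beyond ``z_threshold`` are removed,
    iterating at most ``max_iter`` times and never keeping fewer than
    ``min_keep`` of each class's epochs.  Returns the cleaned EpochSet and
    the per-class report of removed (original) indices.
    """
    report: dict = {}
    keep_mask = np.ones(epochs.n_epochs, dtype=bool)
    for label in np.unique(epochs.labels.astype(str)):
        cls_idx = np.flatnonzero(epochs.labels == label)
        # raw (unnormalized) covariances so amplitude outliers are visible
        covs = np.einsum("eit,ejt->eij", epochs.data[cls_idx],
                         epochs.data[cls_idx]) / epochs.n_samples
        floor = int(np.ceil(min_keep * len(cls_idx)))
        kept = np.arange(len(cls_idx))
        for _ in range(max_iter):
            mean = covs[kept].mean(axis=0)
            dists = np.linalg.norm(covs[kept] - mean, axis=(1, 2))
            sd = dists.std()
            if sd == 0:
                break
            z = (dists - dists.mean()) / sd
            flagged = z > z_threshold
            if not flagged.any():
                break
            if (~flagged).sum() < floor:
                # keep the lowest-distance epochs up to the retention floor
                order = np.argsort(dists)
                kept = kept[order[:floor]]
                break
            kept = kept[~flagged]
        if len(kept) == 0:
            warnings.warn(f"all {label} epochs flagged as outliers; keeping all")
            kept = np.arange(len(cls_idx))
        removed = sorted(set(range(len(cls_idx))) - set(kept.tolist()))
        report[label] = [int(cls_idx[i]) for i in removed]
        keep_mask[cls_idx[removed]] = False
    return epochs.select(np.flatnonzero(keep_mask)), report


def spatial_covariance(epochs: EpochSet) -> CovarianceEstimate:
    """Average trace-normalized channel covariance of one class's epochs."""
    variances = epochs.data.var(axis=(0, 2))
    if np.any(variances == 0):
        bad = [epochs.channel_labels[i] for i in np.flatnonzero(variances == 0)]
        raise ValueError(f"zero-variance channel(s): {bad}")
    covs = _epoch_covariances(epochs.data)
    return CovarianceEstimate(matrix=covs.mean(axis=0), n_epochs_used=epochs.n_epochs)


# ---------------------------------------------------------------------------
# whitened GED (shared by the spatial and temporal stages)

def _whitened_ged(cov_a: np.ndarray, cov_b: np.ndarray, rank_tol: float = 1e-10):
    """Simultaneously diagonalize two PSD matrices via composite whitening.

    Returns (W, eigvals_a, eigvals_b) with W rows as filters, eigenvalues
    descending for class A; per direction the two eigenvalues sum to one.
    """
    composite = cov_a + cov_b
    evals, evecs = linalg.eigh(composite)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    if evals[-1] <= rank_tol * evals[0]:
        logger.warning("composite covariance rank-deficient; applying shrinkage")
        composite = shrunk_covariance(composite, 1e-6)
        evals, evecs = linalg.eigh(composite)
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
    whitener = (evecs / np.sqrt(evals)).T          # P = S^{-1/2} U0^T
    sa = whitener @ cov_a @ whitener.T
    la, U = linalg.eigh((sa + sa.T) / 2.0)
    order = np.argsort(la)[::-1]
    la, U = la[order], U[:, order]
    sb = whitener @ cov_b @ whitener.T
    lb = np.einsum("ij,jk,ki->i", U.T, (sb + sb.T) / 2.0, U)
    W = U.T @ whitener
    return W, la, lb


def _select_extremes(n: int, n_each: int) -> np.ndarray:
    n_each = min(n_each, n // 2)
    return np.concatenate([np.arange(n_each), np.arange(n - n_each, n)])


def csp_fit(cov_a, cov_b, pair=(MI_TARGET, MC_TARGET), n_select: int = 4) -> SpatialFilterBank:
    """Fit CSP filters from two class covariances (CovarianceEstimate or array)."""
    A = cov_a.matrix if isinstance(cov_a, CovarianceEstimate) else np.asarray(cov_a)
    B = cov_b.matrix if isinstance(cov_b, CovarianceEstimate) else np.asarray(cov_b)
    W, la, lb = _whitened_ged(A, B)
    selected = _select_extremes(W.shape[0], n_select)
    return SpatialFilterBank(pair=tuple(pair), W=W, eigvals_a=la, eigvals_b=lb,
                             selected=selected, patterns=linalg.pinv(W))


def apply_spatial(epochs: EpochSet, bank: SpatialFilterBank) -> EpochSet:
    """Project epochs through the selected spatial filters (8 virtual channels)."""
    Wsel = bank.W_selected
    if epochs.n_channels != Wsel.shape[1]:
        raise ValueError("channel count does not match filter bank")
    data = np.einsum("fc,ecs->efs", Wsel, epochs.data)
    labels = [f"CSP{i:02d}" for i in bank.selected]
    return replace(epochs, data=data, channel_labels=labels)


def _temporal_covariance(data: np.ndarray, shrinkage: float) -> np.ndarray:
    """Average trace-normalized T x T covariance; each epoch's virtual-channel
    time courses are the observations; shrunk toward the scaled identity."""
    covs = np.einsum("ecs,ect->est", data, data)
    traces = np.trace(covs, axis1=1, axis2=2)
    cov = (covs / traces[:, None, None]).mean(axis=0)
    return shrunk_covariance(cov, shrinkage)


def ctp_fit(filtered_a: EpochSet, filtered_b: EpochSet, pair=(MI_TARGET, MC_TARGET),
            shrinkage: float = 0.1, n_select: int = 4) -> TemporalFilterBank:
    """Fit the two CTP sets of a pair from spatially filtered 100-Hz epochs.

    The 'first' set is trained on the first four virtual channels (the
    class-A-dominant spatial subset) of both classes' epochs, the 'last'
    set on the last four; each keeps its 4 largest + 4 smallest eigenvector
    filters.
    """
    n_vc = filtered_a.n_channels
    half = n_vc // 2
    sets = {}
    for subset, rows in (("first", slice(0, half)), ("last", slice(n_vc - half, n_vc))):
        cov_a = _temporal_covariance(filtered_a.data[:, rows, :], shrinkage)
        cov_b = _temporal_covariance(filtered_b.data[:, rows, :], shrinkage)
        min_eig = min(linalg.eigvalsh(cov_a)[0], linalg.eigvalsh(cov_b)[0])
        if min_eig <= 0:
            raise ValueError("temporal covariance not positive definite after shrinkage")
        W, la, lb = _whitened_ged(cov_a, cov_b)
        selected = _select_extremes(W.shape[0], n_select)
        sets[subset] = TemporalFilterSet(
            subset=subset, W=W, eigvals_a=la, eigvals_b=lb, selected=selected,
            patterns=linalg.pinv(W), shrinkage=shrinkage,
        )
    return TemporalFilterBank(pair=tuple(pair), sets=sets)


# ---------------------------------------------------------------------------
# full model

def fit_cstp(epochs: EpochSet, pairs=DEFAULT_PAIRS, z_threshold: float = 2.5,
             shrinkage: float = 0.1, n_select: int = 4,
             temporal_rate: float = 100.0, clean: bool = True,
             feature_mode: str = "projection") -> CstpModel:
    """Fit spatial and temporal filter banks for every class pair."""
    spatial, temporal = {}, {}
    for pair in pairs:
        name = pair_name(pair)
        sub = epochs.select(np.flatnonzero(np.isin(epochs.labels, pair)))
        if clean:
            sub, _ = clean_epochs(sub, z_threshold=z_threshold)
        ep_a = sub.select(np.flatnonzero(sub.labels == pair[0]))
        ep_b = sub.select(np.flatnonzero(sub.labels == pair[1]))
        bank = csp_fit(spatial_covariance(ep_a), spatial_covariance(ep_b),
                       pair=pair, n_select=n_select)
        spatial[name] = bank
        fa = downsample_epochs(apply_spatial(ep_a, bank), temporal_rate)
        fb = downsample_epochs(apply_spatial(ep_b, bank), temporal_rate)
        temporal[name] = ctp_fit(fa, fb, pair=pair, shrinkage=shrinkage,
                                 n_select=n_select)
    return CstpModel(spatial=spatial, temporal=temporal, temporal_rate=temporal_rate,
                     input_rate=epochs.sampling_rate, feature_mode=feature_mode)


def extract_features(epochs: EpochSet, model: CstpModel) -> np.ndarray:
    """CSTP features: per pair, 8 virtual channels x 16 temporal projections.

    Each value is the inner product of one virtual channel's 100-Hz time
    course with one selected temporal filter; features are deterministic
    linear functions of the epoch given the fitted model.
    """
    if epochs.sampling_rate != model.input_rate:
        raise ValueError(
            f"epochs sampled at {epochs.sampling_rate} Hz; model expects "
            f"{model.input_rate} Hz"
        )
    blocks = []
    for name, bank in model.spatial.items():
        z = downsample_epochs(apply_spatial(epochs, bank), model.temporal_rate)
        filters = model.temporal[name].stacked_filters()          # 16 x T
        if z.n_samples != filters.shape[1]:
            raise ValueError("sampling-rate mismatch between epochs and model")
        proj = np.einsum("ecs,fs->ecf", z.data, filters)          # e x 8 x 16
        if model.feature_mode == "logvar":
            proj = np.log(proj ** 2 + 1e-12)
        blocks.append(proj.reshape(epochs.n_epochs, -1))
    return np.concatenate(blocks, axis=1)


def cstp_component_maps(epochs: EpochSet, model: CstpModel, pair=DEFAULT_PAIRS[2]):
    """Median component topographies and temporal patterns for one pair.

    For each (spatial subset x temporal subset) combination, the map is the
    median over epochs and filters of the scalp projection of the temporal
    coefficients: ``patterns_spatial @ (Z_subset @ f)``.
    """
    name = pair_name(pair)
    s_bank, t_bank = model.spatial[name], model.temporal[name]
    z = downsample_epochs(apply_spatial(epochs, s_bank), model.temporal_rate)
    half = s_bank.n_selected // 2
    maps = {}
    for s_subset, srows in (("first", slice(0, half)), ("last", slice(half, None))):
        A = s_bank.patterns_selected[:, srows]                    # channels x 4
        for t_subset in ("first", "last"):
            F = t_bank.sets[t_subset].filters                     # 8 x T
            coeff = np.einsum("ecs,fs->ecf", z.data[:, srows, :], F)
            scalp = np.einsum("nc,ecf->enf", A, coeff)            # e x channels x 8
            maps[(s_subset, t_subset)] = np.median(scalp, axis=(0, 2))
    temporal_patterns = {
        subset: t_bank.sets[subset].patterns_selected for subset in ("first", "last")
    }
    return maps, temporal_patterns


# ---------------------------------------------------------------------------
# serialization (JSON manifest + npz arrays)

def save_model(model: CstpModel, path) -> None:
    from pathlib import Path

    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    arrays, manifest = {}, {"temporal_rate": model.temporal_rate,
                            "input_rate": model.input_rate,
                            "feature_mode": model.feature_mode, "pairs": []}
    for name, bank in model.spatial.items():
        manifest["pairs"].append({"name": name, "pair": list(bank.pair)})
        arrays[f"{name}/spatial/W"] = bank.W
        arrays[f"{name}/spatial/eigvals_a"] = bank.eigvals_a
        arrays[f"{name}/spatial/eigvals_b"] = bank.eigvals_b
        arrays[f"{name}/spatial/selected"] = bank.selected
        arrays[f"{name}/spatial/patterns"] = bank.patterns
        for subset, ts in model.temporal[name].sets.items():
            base = f"{name}/temporal/{subset}"
            arrays[f"{base}/W"] = ts.W
            arrays[f"{base}/eigvals_a"] = ts.eigvals_a
            arrays[f"{base}/eigvals_b"] = ts.eigvals_b
            arrays[f"{base}/selected"] = ts.selected
            arrays[f"{base}/patterns"] = ts.patterns
            arrays[f"{base}/shrinkage"] = np.array(ts.shrinkage)
    np.savez(path / "arrays.npz", **arrays)
    (path / "model.json").write_text(json.dumps(manifest, indent=2))


def load_model(path) -> CstpModel:
    from pathlib import Path

    path = Path(path)
    manifest = json.loads((path / "model.json").read_text())
    arrays = np.load(path / "arrays.npz")
    spatial, temporal = {}, {}
    for entry in manifest["pairs"]:
        name, pair = entry["name"], tuple(entry["pair"])
        spatial[name] = SpatialFilterBank(
            pair=pair,
            W=arrays[f"{name}/spatial/W"],
            eigvals_a=arrays[f"{name}/spatial/eigvals_a"],
            eigvals_b=arrays[f"{name}/spatial/eigvals_b"],
            selected=arrays[f"{name}/spatial/selected"],
            patterns=arrays[f"{name}/spatial/patterns"],
        )
        sets = {}
        for subset in ("first", "last"):
            base = f"{name}/temporal/{subset}"
            sets[subset] = TemporalFilterSet(
                subset=subset,
                W=arrays[f"{base}/W"],
                eigvals_a=arrays[f"{base}/eigvals_a"],
                eigvals_b=arrays[f"{base}/eigvals_b"],
                selected=arrays[f"{base}/selected"],
                patterns=arrays[f"{base}/patterns"],
                shrinkage=float(arrays[f"{base}/shrinkage"]),
            )
        temporal[name] = TemporalFilterBank(pair=pair, sets=sets)
    return CstpModel(spatial=spatial, temporal=temporal,
                     temporal_rate=manifest["temporal_rate"],
                     input_rate=manifest.get("input_rate", 250.0),
                     feature_mode=manifest["feature_mode"])
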