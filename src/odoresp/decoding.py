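"""Odor-identity classification at block, region, brain-region-average,
and multi-region levels, with dual-channel integration.

All tiers share one recipe: reduce voxel dimensionality with PCA fitted
on training frames, find discriminant axes with LDA fitted on the single
high-response frame (offset 2 from odor onset; the response window spans
offsets 0–13), re-express every feature frame in LDA space, and classify
the resulting per-trial trajectories with a linear SVM under stratified
5-fold cross-validation.  No test-trial information enters any fit.  The
multi-region tier adds a block-wise PCA (10×10×10 voxel blocks, 90%
variance) before a global PCA to 25 dimensions; dual-channel decoding
runs the block-wise step per channel and concatenates the outputs.  The
accuracy-map tier runs PCA + SVM per 4×4×2 voxel block.

Fitted transforms are linear throughout, so the block-PCA, global-PCA,
and LDA maps can be composed back to voxel space to attribute decoding
influence (identification weights), and applied to all frames of a wider
window to build manifold trajectories.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .preprocess import TrialTensor

__all__ = [
    "DecoderSpec",
    "DecodeResult",
    "region_classify",
    "brainregion_level_classify",
    "multiregion_classify",
    "block_accuracy_map",
    "block_accuracy_gain",
    "identification_weight_map",
    "label_permutation_accuracy",
]


@dataclass(frozen=True)
class DecoderSpec:
    """Hyperparameters of the decoding tiers.

    ``feature_frames`` is a half-open offset range relative to odor onset
    (default (0, 14): offsets 0–13); ``lda_frame`` the single offset LDA is
    fitted on (default 2).  ``pca_variance`` is the region-tier variance
    threshold (0.8), ``region_avg_pca_variance`` the brain-region-average
    tier's (0.998), ``pca1_variance`` the block-wise threshold (0.9), and
    ``pca2_dims`` the global PCA dimension of the multi-region tier (25).
    """

    pca1_variance: float = 0.90
    pca2_dims: int = 25
    pca_variance: float = 0.80
    region_avg_pca_variance: float = 0.998
    lda_frame: int = 2
    feature_frames: tuple[int, int] = (0, 14)
    cv_folds: int = 5
    block_shape: tuple[int, int, int] = (4, 4, 2)
    multiregion_block: tuple[int, int, int] = (10, 10, 10)
    svm_c: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        for v in (self.pca1_variance, self.pca_variance, self.region_avg_pca_variance):
            if not 0 < v <= 1:
                raise ValueError("PCA variance thresholds must be in (0, 1]")
        if not self.feature_frames[0] <= self.lda_frame < self.feature_frames[1]:
            raise ValueError("lda_frame must lie inside feature_frames")


def _as_channel_list(trials) -> list[TrialTensor]:
    return list(trials) if isinstance(trials, (list, tuple)) else [trials]


def _frame_indices(tensor: TrialTensor, spec: DecoderSpec) -> tuple[np.ndarray, int]:
    offs = tensor.window_offsets
    lo, hi = spec.feature_frames
    idx = np.flatnonzero((offs >= lo) & (offs < hi))
    if idx.size != hi - lo:
        raise ValueError(
            f"trial window (offsets {offs[0]}..{offs[-1]}) does not cover "
            f"feature frames [{lo}, {hi})"
        )
    lda_pos = int(np.flatnonzero(offs == spec.lda_frame)[0]) - int(idx[0])
    return idx, lda_pos


def _check_class_counts(labels: np.ndarray, folds: int) -> None:
    classes, counts = np.unique(labels, return_counts=True)
    short = classes[counts < folds]
    if short.size:
        raise ValueError(
            f"class {short[0]!r} has fewer trials than cv folds ({folds}): "
            "stratified folding impossible"
        )


def _fit_frames_pca(x_frames: np.ndarray, n_components, seed: int) -> PCA:
    """Fit PCA on (trials × frames) samples of shape (n, F, V) → samples (n·F, V)."""
    n, f, v = x_frames.shape
    flat = x_frames.reshape(n * f, v)
    max_comp = min(flat.shape)
    if isinstance(n_components, int):
        n_components = min(n_components, max_comp)
    pca = PCA(n_components=n_components, svd_solver="full", random_state=seed)
    pca.fit(flat)
    return pca


def _apply_frames(transform, x_frames: np.ndarray) -> np.ndarray:
    """Apply an sklearn transform frame-wise: (n, F, V) → (n, F, d)."""
    n, f, v = x_frames.shape
    out = transform.transform(x_frames.reshape(n * f, v))
    return out.reshape(n, f, -1)


@dataclass
class _SingleStageTransforms:
    """Region-tier fitted maps: one PCA then LDA (plus the fold's SVM)."""

    pca: PCA
    lda: LinearDiscriminantAnalysis
    svm: SVC

    def project(self, x_frames_per_channel: list[np.ndarray]) -> np.ndarray:
        x = np.concatenate(x_frames_per_channel, axis=2)  # (n, F, Vtot)
        return _apply_frames(self.lda, _apply_frames(self.pca, x))

    def voxel_to_lda_map(self) -> np.ndarray:
        """Compose PCA and LDA into a (d_lda, V) linear map (no offsets)."""
        return self.lda.scalings_[:, : self._n_lda()].T @ self.pca.components_

    def _n_lda(self) -> int:
        return len(self.lda.classes_) - 1


@dataclass
class _MultiRegionTransforms:
    """Multi-region-tier fitted maps: block PCAs → global PCA → LDA (+SVM)."""

    blocks_per_channel: list[list[np.ndarray]]  # voxel index arrays (within mask)
    block_pcas: list[list[PCA]]
    pca2: PCA
    lda: LinearDiscriminantAnalysis
    svm: SVC

    def block_project(self, x_frames_per_channel: list[np.ndarray]) -> np.ndarray:
        parts = []
        for xc, blocks, pcas in zip(
            x_frames_per_channel, self.blocks_per_channel, self.block_pcas
        ):
            for b, pca in zip(blocks, pcas):
                parts.append(_apply_frames(pca, xc[:, :, b]))
        return np.concatenate(parts, axis=2)

    def project(self, x_frames_per_channel: list[np.ndarray]) -> np.ndarray:
        z1 = self.block_project(x_frames_per_channel)
        return _apply_frames(self.lda, _apply_frames(self.pca2, z1))

    def voxel_to_lda_map(self) -> list[np.ndarray]:
        """Per channel, the composed (d_lda, V_masked) linear map."""
        d_lda = len(self.lda.classes_) - 1
        post = self.lda.scalings_[:, :d_lda].T @ self.pca2.components_  # (d, D1)
        maps = []
        col = 0
        for blocks, pcas in zip(self.blocks_per_channel, self.block_pcas):
            n_vox = sum(len(b) for b in blocks)
            m = np.zeros((d_lda, n_vox))
            for b, pca in zip(blocks, pcas):
                db = pca.components_.shape[0]
                m[:, b] += post[:, col : col + db] @ pca.components_
                col += db
            maps.append(m)
        return maps


@dataclass
class DecodeResult:
    """Cross-validated decoding outcome with per-fold fitted transforms."""

    accuracy: float
    fold_accuracies: np.ndarray  # (folds,)
    predictions: np.ndarray  # (trials,) odor label predicted when held out
    classes: np.ndarray
    odor_labels: np.ndarray
    session_ids: np.ndarray
    fold_assignment: np.ndarray  # (trials,) fold in which the trial was tested
    transforms: list  # per-fold transform objects
    spec: DecoderSpec
    tier: str
    channel_masks: list[np.ndarray] | None = None  # voxel indices per channel


def _run_tiered_cv(
    channel_frames: list[np.ndarray],
    labels: np.ndarray,
    sessions: np.ndarray,
    spec: DecoderSpec,
    lda_pos: int,
    fit_fold,
    tier: str,
    channel_masks=None,
) -> DecodeResult:
    n_trials = channel_frames[0].shape[0]
    _check_class_counts(labels, spec.cv_folds)
    skf = StratifiedKFold(n_splits=spec.cv_folds, shuffle=True, random_state=spec.seed)
    predictions = np.empty(n_trials, dtype=object)
    fold_assignment = np.full(n_trials, -1, dtype=int)
    fold_accuracies = []
    transforms = []
    for fold, (train, test) in enumerate(skf.split(np.zeros(n_trials), labels)):
        tf = fit_fold(train)
        z_all = tf.project([xc for xc in channel_frames])
        z_flat = z_all.reshape(n_trials, -1)
        tf.svm.fit(z_flat[train], labels[train])
        pred = tf.svm.predict(z_flat[test])
        predictions[test] = pred
        fold_assignment[test] = fold
        fold_accuracies.append(float((pred == labels[test]).mean()))
        transforms.append(tf)
    return DecodeResult(
        accuracy=float(np.mean(fold_accuracies)),
        fold_accuracies=np.array(fold_accuracies),
        predictions=predictions.astype(str),
        classes=np.unique(labels),
        odor_labels=labels,
        session_ids=sessions,
        fold_assignment=fold_assignment,
        transforms=transforms,
        spec=spec,
        tier=tier,
        channel_masks=channel_masks,
    )


def region_classify(trials, spec: DecoderSpec | None = None, *, pca_variance: float | None = None) -> DecodeResult:
    """Voxel-level odor classification within one region (PCA → LDA → SVM).

    ``trials`` is a TrialTensor or a list of them (one per channel; voxels
    are concatenated).  PCA keeps ``spec.pca_variance`` (default 0.8) of
    the variance of training frames; LDA is fitted on the single
    ``lda_frame`` offset; the SVM classifies trials × (frames × LDA dims).
    """
    spec = spec or DecoderSpec()
    tensors = _as_channel_list(trials)
    fidx, lda_pos = _frame_indices(tensors[0], spec)
    variance = pca_variance if pca_variance is not None else spec.pca_variance
    # (n, F, V) per channel, feature frames only
    frames = [t.values[:, :, fidx].transpose(0, 2, 1) for t in tensors]
    labels = np.asarray(tensors[0].odor_labels, dtype=str)
    sessions = np.asarray(tensors[0].session_ids)

    def fit_fold(train: np.ndarray) -> _SingleStageTransforms:
        x_train = np.concatenate([f[train] for f in frames], axis=2)
        pca = _fit_frames_pca(x_train, variance, spec.seed)
        z_train = _apply_frames(pca, x_train)
        lda = LinearDiscriminantAnalysis()
        lda.fit(z_train[:, lda_pos, :], labels[train])
        svm = SVC(kernel="linear", C=spec.svm_c, decision_function_shape="ovr")
        return _SingleStageTransforms(pca=pca, lda=lda, svm=svm)

    return _run_tiered_cv(frames, labels, sessions, spec, lda_pos, fit_fold, "region")


def brainregion_level_classify(region_trials, spec: DecoderSpec | None = None) -> DecodeResult:
    """Brain-region-average odor classification (PCA variance 0.998).

    Same recipe as :func:`region_classify` but the features are
    region-mean traces instead of voxels.
    """
    spec = spec or DecoderSpec()
    result = region_classify(
        region_trials, spec, pca_variance=spec.region_avg_pca_variance
    )
    return replace(result, tier="region-average")


def _voxel_blocks(coords: np.ndarray, block_shape: tuple[int, int, int]) -> list[np.ndarray]:
    """Group voxel row indices into spatial blocks by integer division."""
    keys = coords // np.asarray(block_shape)
    order = np.lexsort((keys[:, 2], keys[:, 1], keys[:, 0]))
    blocks = []
    start = 0
    sorted_keys = keys[order]
    for i in range(1, len(order) + 1):
        if i == len(order) or not np.array_equal(sorted_keys[i], sorted_keys[start]):
            blocks.append(order[start:i])
            start = i
    return blocks


def multiregion_classify(
    trials,
    spec: DecoderSpec | None = None,
    masks: list[np.ndarray] | None = None,
) -> DecodeResult:
    """Multi-region voxel-level classification, single or dual channel.

    Per channel the (masked) volume is divided into ``multiregion_block``
    voxel blocks; each block gets a PCA keeping 90% of training-frame
    variance; the concatenated block PCs (across blocks and channels) are
    reduced by a second PCA to ``pca2_dims`` (25) dimensions, then LDA on
    the high-response frame and a trajectory SVM as in the region tier.
    ``masks[c]`` selects the voxels of channel c (e.g. the community
    containing most olfactory regions, plus the accuracy-gain regions for
    the second channel).
    """
    spec = spec or DecoderSpec()
    tensors = _as_channel_list(trials)
    if masks is not None:
        tensors = [
            t if m is None else t.select_voxels(np.asarray(m))
            for t, m in zip(tensors, masks)
        ]
    for t in tensors:
        if t.voxel_coords is None:
            raise ValueError("multiregion decoding needs voxel coordinates")
    fidx, lda_pos = _frame_indices(tensors[0], spec)
    frames = [t.values[:, :, fidx].transpose(0, 2, 1) for t in tensors]  # (n,F,V)
    blocks_per_channel = [
        _voxel_blocks(t.voxel_coords, spec.multiregion_block) for t in tensors
    ]
    labels = np.asarray(tensors[0].odor_labels, dtype=str)
    sessions = np.asarray(tensors[0].session_ids)

    def fit_fold(train: np.ndarray) -> _MultiRegionTransforms:
        pcas_per_channel = []
        parts = []
        for xc, blocks in zip(frames, blocks_per_channel):
            pcas = []
            for b in blocks:
                pca = _fit_frames_pca(xc[train][:, :, b], spec.pca1_variance, spec.seed)
                pcas.append(pca)
                parts.append(_apply_frames(pca, xc[train][:, :, b]))
            pcas_per_channel.append(pcas)
        z1_train = np.concatenate(parts, axis=2)
        pca2 = _fit_frames_pca(z1_train, spec.pca2_dims, spec.seed)
        z2_train = _apply_frames(pca2, z1_train)
        lda = LinearDiscriminantAnalysis()
        lda.fit(z2_train[:, lda_pos, :], labels[train])
        svm = SVC(kernel="linear", C=spec.svm_c, decision_function_shape="ovr")
        return _MultiRegionTransforms(
            blocks_per_channel=blocks_per_channel,
            block_pcas=pcas_per_channel,
            pca2=pca2,
            lda=lda,
            svm=svm,
        )

    return _run_tiered_cv(
        frames, labels, sessions, spec, lda_pos, fit_fold, "multiregion",
        channel_masks=masks,
    )


def block_accuracy_map(
    trials,
    spec: DecoderSpec | None = None,
) -> tuple[np.ndarray, dict]:
    """Accuracy map: PCA + SVM odor decoding per small voxel block.

    The volume is divided into ``block_shape`` (4×4×2) voxel blocks; each
    block's features are trials × (voxels × frames × channels), reduced by
    a PCA keeping 90% variance (fitted per training fold) and classified
    with a linear SVM under 5-fold CV.  Returns a per-voxel accuracy array
    (every voxel carries its block's accuracy) and a block → accuracy dict.
    """
    spec = spec or DecoderSpec()
    tensors = _as_channel_list(trials)
    if tensors[0].voxel_coords is None:
        raise ValueError("accuracy map needs voxel coordinates")
    fidx, _ = _frame_indices(tensors[0], spec)
    labels = np.asarray(tensors[0].odor_labels, dtype=str)
    _check_class_counts(labels, spec.cv_folds)
    blocks = _voxel_blocks(tensors[0].voxel_coords, spec.block_shape)
    skf = StratifiedKFold(n_splits=spec.cv_folds, shuffle=True, random_state=spec.seed)
    splits = list(skf.split(np.zeros(labels.size), labels))
    n_vox = tensors[0].values.shape[1]
    voxel_acc = np.zeros(n_vox)
    block_acc: dict[int, float] = {}
    for bi, b in enumerate(blocks):
        feats = np.concatenate(
            [t.values[:, b, :][:, :, fidx].reshape(labels.size, -1) for t in tensors],
            axis=1,
        )
        accs = []
        for train, test in splits:
            pca = PCA(
                n_components=min(spec.pca1_variance, 1.0)
                if feats.shape[1] > 1
                else 1,
                svd_solver="full",
                random_state=spec.seed,
            )
            zt = pca.fit_transform(feats[train])
            svm = SVC(kernel="linear", C=spec.svm_c)
            svm.fit(zt, labels[train])
            accs.append(float((svm.predict(pca.transform(feats[test])) == labels[test]).mean()))
        block_acc[bi] = float(np.mean(accs))
        voxel_acc[b] = block_acc[bi]
    return voxel_acc, block_acc


def block_accuracy_gain(
    dual_trials, single_trials, spec: DecoderSpec | None = None
) -> np.ndarray:
    """Accuracy-gain map: dual-channel block accuracy minus single-channel."""
    dual, _ = block_accuracy_map(dual_trials, spec)
    single, _ = block_accuracy_map(single_trials, spec)
    return dual - single


def identification_weight_map(result: DecodeResult) -> list[np.ndarray]:
    """Per-voxel odor-identification weights from the fitted linear maps.

    Composes the block-PCA, global-PCA, and LDA transformation matrices of
    each fold back to voxel space, takes per-voxel magnitudes on each
    discriminant axis, and averages across folds.  Returns one
    (V, n_classes − 1) array per channel (voxel order = the channel's mask
    order).  Only defined for linear transforms (the pipeline's default).
    """
    if result.tier == "multiregion":
        per_fold = [tf.voxel_to_lda_map() for tf in result.transforms]
        n_channels = len(per_fold[0])
        return [
            np.mean([np.abs(fold[c]).T for fold in per_fold], axis=0)
            for c in range(n_channels)
        ]
    if result.tier in ("region", "region-average"):
        maps = [np.abs(tf.voxel_to_lda_map()).T for tf in result.transforms]
        return [np.mean(maps, axis=0)]
    raise ValueError(f"no weight map for tier {result.tier!r}")


def label_permutation_accuracy(
    classify,
    trials,
    spec: DecoderSpec,
    n_permutations: int = 20,
    seed: int = 0,
    **kwargs,
) -> np.ndarray:
    """Null accuracies from label permutation (chance-level calibration).

    ``classify`` is one of the tier functions; odor labels are permuted
    (seeded) jointly across channels before each run.
    """
    tensors = _as_channel_list(trials)
    rng = np.random.default_rng(seed)
    accs = []
    for i in range(n_permutations):
        perm = rng.permutation(tensors[0].n_trials)
        shuffled = []
        for t in tensors:
            shuffled.append(
                TrialTensor(
                    values=t.values,
                    window_offsets=t.window_offsets,
                    odor_labels=np.asarray(t.odor_labels)[perm],
                    session_ids=t.session_ids,
                    frame_rate=t.frame_rate,
                    voxel_coords=t.voxel_coords,
                    region_id=t.region_id,
                )
            )
        arg = shuffled if isinstance(trials, (list, tuple)) else shuffled[0]
        sub_spec = replace(spec, seed=spec.seed + i + 1)
        accs.append(classify(arg, sub_spec, **kwargs).accuracy)
    return np.array(accs)
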