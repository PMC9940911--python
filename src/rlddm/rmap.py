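"""Voxelwise R-maps, spatial-similarity prediction, permutation testing and
stimulation-volume heat maps.

The R-map is the voxel-by-voxel Pearson correlation, across subjects,
between seed-connectivity strength and a behavioural regressor (here the
DBS-induced change in exploration).  Each subject's similarity to that
map — the spatial correlation over unmasked voxels — is then used to
predict the behavioural change by simple linear regression.  Because the
map is built from the same subjects it is tested on, significance comes
from a permutation scheme that re-runs the *entire* pipeline (R-map →
similarities → correlation) with the behaviour vector shuffled.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
from scipy import stats


@dataclass
class VoxelMapStack:
    """``n_subjects`` aligned 3-D voxel maps on a common grid.

    ``mask`` marks voxels that are valid in every subject; non-finite
    voxels are masked consistently across the stack.
    """

    data: np.ndarray                   # (S, X, Y, Z)
    voxel_size: tuple = (2.0, 2.0, 2.0)
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError("stack must have shape (n_subjects, X, Y, Z)")
        finite = np.all(np.isfinite(self.data), axis=0)
        self.mask = finite if self.mask is None else (np.asarray(self.mask, bool) & finite)

    @property
    def n_subjects(self) -> int:
        return self.data.shape[0]

    @property
    def grid(self) -> tuple:
        return self.data.shape[1:]

    def to_nifti(self, path_prefix: str) -> list:
        """Write one NIfTI volume per subject; returns written paths."""
        affine = np.diag(list(self.voxel_size) + [1.0])
        paths = []
        for s in range(self.n_subjects):
            p = f"{path_prefix}_s{s + 1:02d}.nii"
            nib.save(nib.Nifti1Image(self.data[s].astype(np.float32), affine), p)
            paths.append(p)
        return paths

    @classmethod
    def from_nifti(cls, paths) -> "VoxelMapStack":
        imgs = [nib.load(str(p)) for p in paths]
        grids = {img.shape for img in imgs}
        if len(grids) != 1:
            raise ValueError(f"maps are not on a common grid: {sorted(grids)}")
        vox = tuple(float(v) for v in imgs[0].header.get_zooms()[:3])
        data = np.stack([np.asarray(img.dataobj, dtype=float) for img in imgs])
        return cls(data=data, voxel_size=vox)


@dataclass
class RMap:
    """Voxel grid of across-subject correlation coefficients."""

    values: np.ndarray
    mask: np.ndarray
    threshold: float | None = None

    def to_nifti(self, path: str, voxel_size=(2.0, 2.0, 2.0)) -> str:
        affine = np.diag(list(voxel_size) + [1.0])
        out = np.where(self.mask, self.values, np.nan)
        nib.save(nib.Nifti1Image(out.astype(np.float32), affine), path)
        return path


def _voxel_correlations(data2d: np.ndarray, behaviour: np.ndarray) -> np.ndarray:
    """Pearson r of each column of ``data2d`` (S, V) with ``behaviour`` (S,)."""
    b = behaviour - behaviour.mean()
    x = data2d - data2d.mean(axis=0)
    num = b @ x
    den = np.sqrt((b @ b) * np.sum(x * x, axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = num / den
    return np.clip(r, -1.0, 1.0)


def voxelwise_rmap(stack: VoxelMapStack, behaviour: np.ndarray,
                   threshold: float | None = None) -> RMap:
    """Correlate every voxel's connectivity with the behavioural regressor.

    ``threshold`` zeroes voxels with |r| below the cut (a display aid; the
    downstream similarity computation uses the unthresholded map by
    default).
    """
    behaviour = np.asarray(behaviour, dtype=float)
    if len(behaviour) != stack.n_subjects:
        raise ValueError("behaviour vector length must equal n_subjects")
    if np.std(behaviour) == 0:
        raise ValueError("behaviour regressor has zero variance")
    if stack.n_subjects == 2:
        warnings.warn("n_subjects = 2: every voxel correlation is +/-1")
    elif stack.n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    vals = np.zeros(stack.grid)
    flat = stack.data[:, stack.mask]
    r = _voxel_correlations(flat, behaviour)
    if threshold is not None:
        r = np.where(np.abs(r) >= threshold, r, 0.0)
    vals[stack.mask] = r
    return RMap(values=vals, mask=stack.mask.copy(), threshold=threshold)


def spatial_similarity(individual_map: np.ndarray, rmap: RMap) -> float:
    """Pearson correlation between a subject map and the R-map over the
    shared unmasked, finite voxels."""
    individual_map = np.asarray(individual_map, dtype=float)
    if individual_map.shape != rmap.values.shape:
        raise ValueError("map and R-map grids differ")
    m = rmap.mask & np.isfinite(individual_map)
    if not m.any():
        raise ValueError("no overlapping unmasked voxels")
    r, _ = stats.pearsonr(individual_map[m], rmap.values[m])
    return float(r)


def predict_behaviour(similarities: np.ndarray, behaviour: np.ndarray):
    """Simple linear regression of behaviour on map similarity.

    Returns ``(R^2, two-sided p)``.
    """
    similarities = np.asarray(similarities, dtype=float)
    behaviour = np.asarray(behaviour, dtype=float)
    if len(similarities) < 3:
        raise ValueError("need at least 3 subjects")
    if np.std(similarities) == 0 or np.std(behaviour) == 0:
        raise ValueError("zero-variance input")
    res = stats.linregress(similarities, behaviour)
    return float(res.rvalue ** 2), float(res.pvalue)


def _pipeline_r(flat: np.ndarray, behaviour: np.ndarray) -> float:
    """R-map -> per-subject similarity -> correlation with behaviour."""
    r_map = _voxel_correlations(flat, behaviour)
    fm = flat - flat.mean(axis=1, keepdims=True)
    rm = r_map - r_map.mean()
    num = fm @ rm
    den = np.sqrt(np.sum(fm * fm, axis=1) * (rm @ rm))
    sims = num / den
    return float(stats.pearsonr(sims, behaviour)[0])


@dataclass
class PermutationResult:
    observed_r: float
    p_two_sided: float
    p_directional: float
    null: np.ndarray


def permutation_test(stack: VoxelMapStack, behaviour: np.ndarray,
                     n_perm: int = 1000,
                     rng: np.random.Generator | None = None) -> PermutationResult:
    """Permutation test of the similarity-predicts-behaviour correlation.

    The full pipeline is recomputed for each of ``n_perm`` shuffles of the
    behaviour vector; p-values use add-one smoothing, so they lie in
    (0, 1].  Both the two-sided (|R|) and directional p are reported.
    """
    if rng is None:
        rng = np.random.default_rng()
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    behaviour = np.asarray(behaviour, dtype=float)
    flat = stack.data[:, stack.mask]
    observed = _pipeline_r(flat, behaviour)
    null = np.empty(n_perm)
    for k in range(n_perm):
        null[k] = _pipeline_r(flat, rng.permutation(behaviour))
    p_two = (1 + np.sum(np.abs(null) >= abs(observed))) / (n_perm + 1)
    p_dir = (1 + np.sum(null >= observed)) / (n_perm + 1)
    return PermutationResult(observed_r=observed, p_two_sided=float(p_two),
                             p_directional=float(p_dir), null=null)


def heatmap_overlap(stim_volumes: np.ndarray, region_masks: dict,
                    prob_threshold: float = 0.5):
    """Stimulation-volume n-map and weighted overlap with named regions.

    ``stim_volumes`` is a binary stack (S, X, Y, Z); the n-map counts, per
    voxel, how many subject volumes cover it.  Probabilistic region images
    are binarised at ``prob_threshold``; each region's score is the sum of
    n-map values inside its mask (the weighted sum of overlapping voxels).
    Grids must already match — there is no silent resampling.
    """
    stim = np.asarray(stim_volumes)
    if stim.ndim != 4:
        raise ValueError("stim_volumes must have shape (n_subjects, X, Y, Z)")
    nmap = stim.astype(np.int64).sum(axis=0)
    scores = {}
    for name, region in region_masks.items():
        region = np.asarray(region)
        if region.shape != nmap.shape:
            raise ValueError(
                f"region {name!r} grid {region.shape} does not match the "
                f"stimulation grid {nmap.shape}; resample before calling")
        binary = region >= prob_threshold if region.dtype != bool else region
        scores[name] = float(nmap[binary].sum())
    return nmap, scores
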