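"""Lesion-aware EM tissue segmentation.

The cross-sectional core of the pipeline: a Gaussian-mixture EM with
spatially varying anatomical priors classifies GM/WM/CSF on the T1; white
matter lesions are detected as FLAIR hyperintensities against
normal-appearing white matter (NAWM) statistics, filled on the T1 with
WM-like intensities, and the filled image is segmented again.  The outer
loop repeats until the tissue and lesion maps stop changing.

The mixture is univariate (T1 intensity only, one scalar variance per
class); the FLAIR enters solely through lesion detection, mirroring the
role split between the two contrasts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .grid import VolumeGrid
from .preproc import PriorSet

_CLASSES = ("gm", "wm", "csf")


@dataclass
class SegmentConfig:
    """Tunables of the segmentation stage.

    ``kappa`` is the FLAIR hyperintensity threshold in NAWM standard
    deviations; ``p_wm_min`` the minimum WM prior for a lesion candidate;
    ``min_component_mm3`` removes speckle components.  The outer loop is
    declared converged when the Dice overlap of successive lesion masks
    reaches ``lesion_dice_tol`` (or both masks are empty) and fewer than
    ``label_change_tol`` of the hard labels changed.
    """

    kappa: float = 3.0
    p_wm_min: float = 0.5
    min_component_mm3: float = 15.0
    em_tol: float = 1e-5
    em_max_iter: int = 100
    max_outer: int = 10
    lesion_dice_tol: float = 0.95
    label_change_tol: float = 1e-3
    prior_floor: float = 0.01
    fill_seed: int = 12345


@dataclass
class TissueModel:
    """Per-class Gaussian intensity parameters of the fitted mixture."""

    means: dict
    variances: dict
    mixing: dict

    def __post_init__(self):
        if any(v <= 0 for v in self.variances.values()):
            raise ValueError("variances must be strictly positive")
        tot = sum(self.mixing.values())
        if abs(tot - 1.0) > 1e-6:
            raise ValueError("mixing weights must sum to 1")


@dataclass
class Segmentation:
    """Per-voxel tissue probabilities, hard labels and volumes in ml.

    Probabilities sum to 1 at every in-mask voxel and are zero outside.
    ``hard_labels`` uses codes 0=background, 1=csf, 2=gm, 3=wm, 5=lesion
    (matching the phantom label codes where they overlap).
    """

    prob_gm: VolumeGrid
    prob_wm: VolumeGrid
    prob_csf: VolumeGrid
    prob_lesion: VolumeGrid
    hard_labels: VolumeGrid
    volumes_ml: dict

    @property
    def pv_prob(self) -> VolumeGrid:
        """Parenchyma probability: GM + WM + lesion."""
        return self.prob_gm.with_data(
            self.prob_gm.data + self.prob_wm.data + self.prob_lesion.data)


@dataclass
class LesionMask:
    mask: VolumeGrid
    lesion_volume_ml: float
    component_count: int


def _prepare_priors(priors: PriorSet, mask: np.ndarray, floor: float):
    """Floored, in-mask-normalized spatial priors (sum to 1 per voxel)."""
    stack = np.stack([priors.gm_prior.data, priors.wm_prior.data,
                      priors.csf_prior.data]).astype(float)
    stack = np.clip(stack, floor, None)
    stack /= stack.sum(axis=0, keepdims=True)
    return {c: stack[i][mask] for i, c in enumerate(_CLASSES)}


def _em_fit(y: np.ndarray, pri: dict, config: SegmentConfig):
    """EM core: Gaussian mixture with per-sample prior weights.

    E-step: gamma_c(x) proportional to prior_c(x) * N(y(x); mu_c,
    sigma_c^2); M-step: closed-form responsibility-weighted updates.
    Iterates until the relative log-likelihood change drops below
    ``em_tol``.  Returns (gamma, mu, var, trace).
    """
    classes = list(pri)
    var_floor = (1e-3 * max(np.ptp(y), 1.0)) ** 2
    mu = {c: float(np.sum(pri[c] * y) / np.sum(pri[c])) for c in classes}
    # flat priors give every class the same weighted mean; spread the
    # inits over intensity quantiles so EM can break the symmetry
    if max(mu.values()) - min(mu.values()) < 1e-6 * max(np.ptp(y), 1.0):
        qs = np.quantile(y, (np.arange(len(classes)) + 0.5) / len(classes))
        mu = {c: float(q) for c, q in zip(classes, qs)}
    var = {}
    for c in classes:
        v = float(np.sum(pri[c] * (y - mu[c]) ** 2) / np.sum(pri[c]))
        var[c] = max(v, var_floor)

    trace = []
    gamma = None
    for _ in range(config.em_max_iter):
        dens = {}
        for c in classes:
            dens[c] = pri[c] * np.exp(
                -0.5 * (y - mu[c]) ** 2 / var[c]
            ) / np.sqrt(2 * np.pi * var[c])
        total = np.maximum(sum(dens.values()), 1e-300)
        loglik = float(np.sum(np.log(total)))
        gamma = {c: dens[c] / total for c in classes}
        for c in classes:
            w = gamma[c].sum()
            if w < 10:
                raise ValueError(f"class collapse: {c} has total "
                                 f"responsibility {w:.1f} < 10 voxels")
            mu[c] = float(np.sum(gamma[c] * y) / w)
            var[c] = max(float(np.sum(gamma[c] * (y - mu[c]) ** 2) / w),
                         var_floor)
        if trace and abs(loglik - trace[-1]) <= (
                config.em_tol * abs(trace[-1])):
            trace.append(loglik)
            break
        trace.append(loglik)
    return gamma, mu, var, trace


def fit_intensity_mixture(values, n_classes: int = 2,
                          config: SegmentConfig | None = None):
    """Fit a flat-prior 1D Gaussian mixture to an intensity sample.

    Returns ``(means, variances, loglik_trace)`` with means ascending.
    """
    config = config or SegmentConfig()
    y = np.asarray(values, dtype=float).ravel()
    pri = {k: np.full(y.size, 1.0 / n_classes) for k in range(n_classes)}
    _, mu, var, trace = _em_fit(y, pri, config)
    order = np.argsort([mu[k] for k in range(n_classes)])
    return ([mu[k] for k in order], [var[k] for k in order], trace)


def em_segment(t1: VolumeGrid, priors: PriorSet, mask: VolumeGrid,
               config: SegmentConfig | None = None):
    """EM tissue classification with spatially varying anatomical priors.

    Returns a lesion-free :class:`Segmentation`, the fitted
    :class:`TissueModel` and the per-iteration log-likelihood trace.
    """
    config = config or SegmentConfig()
    m = np.asarray(mask.data, dtype=bool)
    if not m.any():
        raise ValueError("empty mask")
    y = np.asarray(t1.data, dtype=float)[m]
    pri = _prepare_priors(priors, m, config.prior_floor)
    gamma, mu, var, loglik_trace = _em_fit(y, pri, config)
    n = float(y.size)
    model = TissueModel(
        means=dict(mu), variances=dict(var),
        mixing={c: float(gamma[c].sum() / n) for c in _CLASSES})
    seg = _build_segmentation(t1, m, gamma, lesion=None)
    return seg, model, loglik_trace


def _build_segmentation(t1: VolumeGrid, mask: np.ndarray, gamma: dict,
                        lesion: np.ndarray | None) -> Segmentation:
    vox_ml = t1.voxel_volume_ml
    maps = {}
    lesion_in = lesion[mask] if lesion is not None else np.zeros(
        int(mask.sum()), dtype=bool)
    scale = np.where(lesion_in, 0.0, 1.0)
    for c in _CLASSES:
        full = np.zeros(t1.shape)
        full[mask] = gamma[c] * scale
        maps[c] = t1.with_data(full)
    les_full = np.zeros(t1.shape)
    les_full[mask] = lesion_in.astype(float)
    prob_lesion = t1.with_data(les_full)

    # hard labels: background 0, csf 1, gm 2, wm 3, lesion 5
    stack = np.stack([maps["csf"].data, maps["gm"].data, maps["wm"].data])
    hard = np.zeros(t1.shape, dtype=np.uint8)
    hard[mask] = (1 + np.argmax(stack, axis=0))[mask]
    hard[les_full > 0.5] = 5
    volumes = {c: float(maps[c].data.sum() * vox_ml) for c in _CLASSES}
    volumes["lesion"] = float(les_full.sum() * vox_ml)
    volumes["pv"] = volumes["gm"] + volumes["wm"] + volumes["lesion"]
    return Segmentation(
        prob_gm=maps["gm"], prob_wm=maps["wm"], prob_csf=maps["csf"],
        prob_lesion=prob_lesion,
        hard_labels=t1.with_data(hard), volumes_ml=volumes)


def detect_lesions(flair_in_t1: VolumeGrid, seg: Segmentation,
                   model: TissueModel, priors: PriorSet,
                   config: SegmentConfig | None = None,
                   current_lesions: np.ndarray | None = None) -> LesionMask:
    """FLAIR-hyperintensity lesion detection against NAWM statistics.

    A voxel is a lesion candidate when (i) its FLAIR intensity exceeds
    mu_NAWM + kappa * sigma_NAWM, where the NAWM statistics are computed
    over currently WM-labeled voxels excluding current lesions, (ii) its WM
    prior is at least ``p_wm_min`` and (iii) its CSF probability is below
    0.5.  Connected components smaller than ``min_component_mm3`` are
    removed.
    """
    config = config or SegmentConfig()
    fl = np.asarray(flair_in_t1.data, dtype=float)
    wm_vox = np.asarray(seg.hard_labels.data) == 3
    if current_lesions is not None:
        wm_vox &= ~current_lesions
    if not wm_vox.any():
        raise ValueError("no WM voxels available to estimate NAWM statistics")
    mu_nawm = float(fl[wm_vox].mean())
    sd_nawm = float(fl[wm_vox].std())
    thr_flair = mu_nawm + config.kappa * sd_nawm
    # GM guard: GM is brighter than WM on FLAIR, so at very low noise the
    # NAWM threshold alone would flag GM/WM partial-volume voxels; a true
    # hyperintensity must also exceed the GM level by the NAWM noise margin
    gm_vox = np.asarray(seg.hard_labels.data) == 2
    if gm_vox.any():
        thr_flair = max(thr_flair, float(fl[gm_vox].mean())
                        + config.kappa * sd_nawm)
    # noise speckle is rejected by requiring hyperintensity to survive a
    # 1-voxel blur: single-voxel noise excursions do not, lesions (several
    # voxels across) do
    fl_smooth = ndimage.gaussian_filter(fl, 1.0)
    cand = (
        (fl > thr_flair)
        & (fl_smooth > thr_flair)
        & (np.asarray(priors.wm_prior.data) >= config.p_wm_min)
        # CSF veto: a candidate is rejected as fluid only when both the
        # current posterior and the atlas agree it is CSF — unfilled
        # T1-hypointense lesions pick up spurious CSF posteriors on the
        # first pass and must stay eligible for filling
        & ((np.asarray(seg.prob_csf.data) < 0.5)
           | (np.asarray(priors.csf_prior.data) < 0.5))
        & (np.asarray(seg.hard_labels.data) > 0)
    )
    vox_mm3 = flair_in_t1.voxel_volume_ml * 1000.0
    lab, n = ndimage.label(cand)
    if n:
        sizes = ndimage.sum_labels(np.ones_like(lab), lab,
                                   index=np.arange(1, n + 1))
        keep = np.flatnonzero(sizes * vox_mm3 >= config.min_component_mm3) + 1
        cand = np.isin(lab, keep)
        # full-width-half-maximum volumetry: bound each lesion at half its
        # height above NAWM, so the partial-volume ring between the kappa
        # threshold and the half crossing does not inflate the volume
        for k in keep:
            comp = lab == k
            h = np.percentile(fl[comp], 90)
            cut = mu_nawm + 0.5 * (h - mu_nawm)
            if cut > thr_flair:
                cand[comp & (fl <= cut)] = False
        n = int(ndimage.label(cand)[1])
    return LesionMask(
        mask=flair_in_t1.with_data(cand),
        lesion_volume_ml=float(cand.sum() * vox_mm3 / 1000.0),
        component_count=int(n),
    )


def fill_lesions(t1: VolumeGrid, lesions: LesionMask, model: TissueModel,
                 rng_seed: int = 12345) -> VolumeGrid:
    """Replace lesion voxels with draws from the WM intensity model."""
    mask = np.asarray(lesions.mask.data, dtype=bool)
    if not mask.any():
        return t1
    rng = np.random.default_rng(rng_seed)
    out = np.array(t1.data, dtype=float, copy=True)
    out[mask] = rng.normal(model.means["wm"],
                           np.sqrt(model.variances["wm"]), int(mask.sum()))
    return t1.with_data(out)


def _dice(a: np.ndarray, b: np.ndarray) -> float:
    sa, sb = a.sum(), b.sum()
    if sa == 0 and sb == 0:
        return 1.0
    return 2.0 * float(np.sum(a & b)) / float(sa + sb)


@dataclass
class IterationLog:
    rows: list = field(default_factory=list)  # (iter, loglik, lesion_dice)

    def to_csv(self, path):
        import csv

        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["iteration", "log_likelihood", "lesion_dice"])
            w.writerows(self.rows)


def iterate_segmentation(t1: VolumeGrid, flair_in_t1: VolumeGrid,
                         priors: PriorSet, mask: VolumeGrid,
                         config: SegmentConfig | None = None,
                         fill: bool = True):
    """Alternate EM segmentation, lesion detection and lesion filling.

    Loops {EM on the current filled T1 -> detect lesions -> fill lesions}
    until the lesion mask and hard labels stabilize, with a hard cap of
    ``max_outer`` outer iterations (non-convergence is flagged, not raised).

    Returns ``(segmentation, lesion_mask, model, filled_t1, info)``; the
    final segmentation's lesion probability comes from the final mask, with
    tissue probabilities renormalized around it.
    """
    config = config or SegmentConfig()
    current_t1 = t1
    prev_lesions = np.zeros(t1.shape, dtype=bool)
    prev_hard = None
    converged = False
    log = IterationLog()
    seg = model = trace = None
    for it in range(config.max_outer):
        seg, model, trace = em_segment(current_t1, priors, mask, config)
        lesions = detect_lesions(flair_in_t1, seg, model, priors, config,
                                 current_lesions=prev_lesions)
        les = np.asarray(lesions.mask.data, dtype=bool)
        current_t1 = (fill_lesions(t1, lesions, model, config.fill_seed)
                      if fill else t1)
        hard = np.asarray(seg.hard_labels.data)
        dice = _dice(prev_lesions, les)
        log.rows.append((it, trace[-1], dice))
        if prev_hard is not None:
            changed = float(np.mean(hard != prev_hard))
            if (dice >= config.lesion_dice_tol or
                    (not prev_lesions.any() and not les.any())) \
                    and changed < config.label_change_tol:
                prev_lesions = les
                converged = True
                break
        prev_hard = hard
        prev_lesions = les
    final_lesions = LesionMask(
        mask=t1.with_data(prev_lesions),
        lesion_volume_ml=float(prev_lesions.sum() * t1.voxel_volume_ml),
        component_count=int(ndimage.label(prev_lesions)[1]),
    )
    gamma = {c: np.asarray(getattr(seg, f"prob_{c}").data)[
        np.asarray(mask.data, dtype=bool)] for c in _CLASSES}
    seg = _build_segmentation(t1, np.asarray(mask.data, dtype=bool), gamma,
                              lesion=prev_lesions)
    info = {"converged": converged, "outer_iterations": it + 1,
            "em_loglik_final": trace[-1] if trace else None}
    return seg, final_lesions, model, current_t1, info


def tissue_volumes(seg: Segmentation) -> dict:
    """Per-class volumes in ml; PV = GM + WM + lesion."""
    return dict(seg.volumes_ml)
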