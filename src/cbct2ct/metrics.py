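"""Evaluation stack: HU accuracy, ROI statistics, contour agreement, gamma.

HU accuracy over the pixels involved (an evaluation mask, by default the
body):

    MAE  = (1/N) sum |yhat - y|
    RMSE = sqrt((1/N) sum (yhat - y)^2)
    PSNR = 10 log10(Max_p^2 / MSE)        [dB; +inf for a perfect match]

Contour agreement uses the Dice similarity coefficient and the mean
distance to agreement (symmetric mean surface distance, spacing-aware, mm).

Dose agreement uses global 3D gamma analysis: for every reference voxel at
or above a low-dose threshold (default 10% of prescription),

    gamma = min over candidate points p of
            sqrt((dD(p)/D_c)^2 + (r(p)/dta)^2)

with dD the dose difference relative to the *prescription*-normalized
criterion D_c (global normalization), r the distance to the candidate, and
candidates on a sub-voxel grid out to a configurable search radius.  A
voxel passes when gamma <= 1 (the boundary counts as a pass).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .phantom import ContourMask, DoseGrid

#: Default PSNR peak: the width of the standard HU normalization range.
DEFAULT_MAX_P = 2000.0


# ------------------------------------------------------------- HU accuracy
def _masked_diff(test, reference, mask):
    y = np.asarray(reference, dtype=np.float64)
    yh = np.asarray(test, dtype=np.float64)
    if y.shape != yh.shape:
        raise ValueError(f"shape mismatch {yh.shape} vs {y.shape}")
    if mask is None:
        mask = np.ones(y.shape, bool)
    else:
        mask = np.asarray(mask, bool)
        if mask.shape != y.shape:
            raise ValueError("mask grid does not match the images")
    if not mask.any():
        raise ValueError("empty evaluation mask")
    return yh[mask] - y[mask]


def mae(test, reference, mask=None) -> float:
    """Mean absolute error over the evaluation mask (HU)."""
    d = _masked_diff(test, reference, mask)
    return float(np.mean(np.abs(d)))


def rmse(test, reference, mask=None) -> float:
    """Root mean square error over the evaluation mask (HU)."""
    d = _masked_diff(test, reference, mask)
    return float(np.sqrt(np.mean(d * d)))


def psnr(test, reference, mask=None, max_p: float = DEFAULT_MAX_P) -> float:
    """Peak signal-to-noise ratio in dB; +inf for an exact match."""
    d = _masked_diff(test, reference, mask)
    mse = float(np.mean(d * d))
    if mse == 0.0:
        return float("inf")
    return float(10.0 * np.log10(max_p * max_p / mse))


def hu_histogram(image, mask, bin_edges) -> np.ndarray:
    """Counts of masked pixels per bin; out-of-range values go to end bins."""
    edges = np.asarray(bin_edges, dtype=np.float64)
    if edges.ndim != 1 or len(edges) < 2:
        raise ValueError("need at least two bin edges")
    if np.any(np.diff(edges) <= 0):
        raise ValueError("bin edges must be strictly increasing")
    img = np.asarray(image, dtype=np.float64)
    if mask is None:
        vals = img.ravel()
    else:
        vals = img[np.asarray(mask, bool)]
    clipped = np.clip(vals, edges[0], np.nextafter(edges[-1], -np.inf))
    counts, _ = np.histogram(clipped, bins=edges)
    return counts


def roi_stats(image, roi: ContourMask | np.ndarray) -> tuple[float, float]:
    """(mean, sd) of HU inside the ROI; population sd (ddof = 0)."""
    m = roi.mask if isinstance(roi, ContourMask) else np.asarray(roi, bool)
    img = np.asarray(image, dtype=np.float64)
    if m.shape != img.shape:
        raise ValueError("ROI grid does not match the image")
    if not m.any():
        raise ValueError("empty ROI")
    vals = img[m]
    return float(vals.mean()), float(vals.std(ddof=0))


# -------------------------------------------------------- contour agreement
def _as_mask(x) -> ContourMask:
    if isinstance(x, ContourMask):
        return x
    return ContourMask(np.asarray(x, bool))


def dsc(a, b) -> float:
    """Dice similarity coefficient 2|A n B| / (|A| + |B|); both empty -> 1."""
    am, bm = _as_mask(a), _as_mask(b)
    if am.shape != bm.shape:
        raise ValueError("masks must share a grid")
    na, nb = int(am.mask.sum()), int(bm.mask.sum())
    if na + nb == 0:
        return 1.0
    inter = int((am.mask & bm.mask).sum())
    return 2.0 * inter / (na + nb)


def _boundary(mask: np.ndarray) -> np.ndarray:
    return mask & ~ndimage.binary_erosion(mask)


def mda(a, b) -> float:
    """Mean distance to agreement in mm: symmetric mean surface distance."""
    am, bm = _as_mask(a), _as_mask(b)
    if am.shape != bm.shape:
        raise ValueError("masks must share a grid")
    if am.spacing != bm.spacing:
        raise ValueError("masks must share spacing")
    if not am.mask.any() or not bm.mask.any():
        raise ValueError("distance metrics need non-empty masks")
    ba, bb = _boundary(am.mask), _boundary(bm.mask)
    spacing = am.spacing
    # distance (mm) from every voxel to the nearest boundary voxel of the
    # other contour, read off at this contour's boundary
    d_to_b = ndimage.distance_transform_edt(~bb, sampling=spacing)
    d_to_a = ndimage.distance_transform_edt(~ba, sampling=spacing)
    return float(0.5 * (d_to_b[ba].mean() + d_to_a[bb].mean()))


# ------------------------------------------------------------ gamma engine
@dataclass(frozen=True)
class GammaConfig:
    dose_criterion: float = 1.0      # percent of the prescription dose
    dta: float = 1.0                 # distance-to-agreement criterion, mm
    low_dose_threshold: float = 0.10  # fraction of prescription
    search_radius: float = 3.0       # multiples of dta
    # candidate spacing as a fraction of the smallest voxel dimension:
    # keeping the sub-voxel grid independent of dta makes candidate sets
    # nested as the criteria loosen, so pass rates respond monotonically
    interp_step: float = 0.1

    def __post_init__(self):
        if min(self.dose_criterion, self.dta, self.low_dose_threshold,
               self.interp_step) <= 0:
            raise ValueError("gamma criteria must be positive")
        if self.search_radius < 1:
            raise ValueError("search radius must be >= 1 (x dta)")

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}

    @classmethod
    def from_dict(cls, d: dict) -> "GammaConfig":
        return cls(**d)


def _candidate_offsets(cfg: GammaConfig, spacing) -> np.ndarray:
    """Sub-voxel candidate displacements (mm), sorted by distance."""
    R = cfg.search_radius * cfg.dta
    step = cfg.interp_step * float(np.min(spacing))
    k = int(np.floor(R / step + 1e-9))
    ax = np.arange(-k, k + 1, dtype=np.float64) * step
    oz, oy, ox = np.meshgrid(ax, ax, ax, indexing="ij")
    offs = np.stack([oz.ravel(), oy.ravel(), ox.ravel()], axis=1)
    d2 = (offs * offs).sum(axis=1)
    keep = d2 <= R * R + 1e-9
    offs, d2 = offs[keep], d2[keep]
    order = np.argsort(d2, kind="stable")
    return offs[order]


def _check_pair(ref: DoseGrid, test: DoseGrid):
    if ref.values.shape != test.values.shape:
        raise ValueError("dose grids must share shape")
    if ref.spacing != test.spacing:
        raise ValueError("dose grids must share spacing")
    if ref.prescription <= 0:
        raise ValueError("prescription must be positive")


def gamma_index(ref: DoseGrid, test: DoseGrid,
                cfg: GammaConfig = GammaConfig()
                ) -> tuple[np.ndarray, float]:
    """Gamma map (NaN outside the low-dose threshold) and pass rate in %.

    Exact minimum over the full sub-voxel candidate grid; candidates are
    visited in order of increasing distance so the search stops as soon as
    the distance term alone exceeds every running minimum.
    """
    _check_pair(ref, test)
    p = ref.prescription
    D_c = cfg.dose_criterion / 100.0 * p
    spacing = np.asarray(ref.spacing, dtype=np.float64)
    shape = np.asarray(ref.values.shape)

    eval_mask = ref.values >= cfg.low_dose_threshold * p
    gamma_map = np.full(ref.values.shape, np.nan)
    if not eval_mask.any():
        return gamma_map, float("nan")

    vox = np.argwhere(eval_mask).astype(np.float64)      # index coords
    pos_mm = vox * spacing
    ref_dose = ref.values[eval_mask].astype(np.float64)
    offs = _candidate_offsets(cfg, ref.spacing)
    dist2 = (offs * offs).sum(axis=1)
    dta2 = cfg.dta * cfg.dta

    best = np.full(len(vox), np.inf)
    chunk = max(1, int(5e6 // max(len(vox), 1)))
    i = 0
    while i < len(offs):
        j = min(i + chunk, len(offs))
        # distance term is non-decreasing: once it alone exceeds every
        # current minimum, no later candidate can improve any voxel
        if dist2[i] / dta2 >= best.max():
            break
        o = offs[i:j]
        cand_idx = (pos_mm[:, None, :] + o[None, :, :]) / spacing  # V,O,3
        inside = np.all((cand_idx >= 0) & (cand_idx <= shape - 1), axis=2)
        flat = cand_idx.reshape(-1, 3).T
        dose = ndimage.map_coordinates(test.values.astype(np.float64), flat,
                                       order=1, mode="nearest")
        dose = dose.reshape(len(vox), j - i)
        dd = (dose - ref_dose[:, None]) / D_c
        g2 = dd * dd + dist2[i:j][None, :] / dta2
        g2 = np.where(inside, g2, np.inf)
        best = np.minimum(best, g2.min(axis=1))
        i = j

    g = np.sqrt(best)
    gamma_map[eval_mask] = g
    pass_rate = 100.0 * float(np.mean(g <= 1.0 + 1e-9))
    return gamma_map, pass_rate


def gamma_index_bruteforce(ref: DoseGrid, test: DoseGrid,
                           cfg: GammaConfig = GammaConfig()
                           ) -> tuple[np.ndarray, float]:
    """Reference implementation: explicit per-voxel loop over the full
    candidate grid with hand-written trilinear interpolation."""
    _check_pair(ref, test)
    p = ref.prescription
    D_c = cfg.dose_criterion / 100.0 * p
    spacing = np.asarray(ref.spacing, dtype=np.float64)
    shape = ref.values.shape
    tvals = test.values.astype(np.float64)
    offs = _candidate_offsets(cfg, ref.spacing)
    dist2 = (offs * offs).sum(axis=1)
    dta2 = cfg.dta * cfg.dta
    eval_mask = ref.values >= cfg.low_dose_threshold * p
    gamma_map = np.full(shape, np.nan)

    def trilinear(pt):
        i0 = np.floor(pt).astype(int)
        f = pt - i0
        acc = 0.0
        for dz in (0, 1):
            for dy in (0, 1):
                for dx in (0, 1):
                    idx = i0 + (dz, dy, dx)
                    idx = np.minimum(np.maximum(idx, 0),
                                     np.asarray(shape) - 1)
                    wz = f[0] if dz else 1 - f[0]
                    wy = f[1] if dy else 1 - f[1]
                    wx = f[2] if dx else 1 - f[2]
                    acc += wz * wy * wx * tvals[tuple(idx)]
        return acc

    for v in np.argwhere(eval_mask):
        pos = v * spacing
        rd = float(ref.values[tuple(v)])
        best = np.inf
        for o, d2 in zip(offs, dist2):
            idx = (pos + o) / spacing
            if np.any(idx < 0) or np.any(idx > np.asarray(shape) - 1):
                continue
            dd = (trilinear(idx) - rd) / D_c
            best = min(best, dd * dd + d2 / dta2)
        gamma_map[tuple(v)] = np.sqrt(best)
    vals = gamma_map[eval_mask]
    pass_rate = 100.0 * float(np.mean(vals <= 1.0 + 1e-9))
    return gamma_map, pass_rate


# ------------------------------------------------------------- aggregation
@dataclass
class EvalCase:
    """One evaluation case: image pair, optional contours and dose pair."""

    case_id: str
    reference: np.ndarray                       # ground-truth CT, HU
    test: np.ndarray                            # sCT (or raw CBCT), HU
    eval_mask: np.ndarray | None = None         # pixels involved; None = all
    contours: dict[str, tuple[ContourMask, ContourMask]] = field(
        default_factory=dict)                   # organ -> (reference, test)
    dose: tuple[DoseGrid, DoseGrid] | None = None
    max_p: float = DEFAULT_MAX_P


def evaluation_report(cases: list[EvalCase],
                      gamma_cfg: GammaConfig = GammaConfig(),
                      out_csv=None, out_json=None):
    """Per-case metric table plus mean +/- sd summary (sample sd, ddof=1).

    Returns (DataFrame, summary dict); optionally writes CSV and JSON.
    """
    import pandas as pd

    if not cases:
        raise ValueError("need at least one evaluation case")
    rows = []
    for case in cases:
        m = case.eval_mask
        rows.append({"case": case.case_id, "metric": "mae_hu",
                     "value": mae(case.test, case.reference, m)})
        rows.append({"case": case.case_id, "metric": "rmse_hu",
                     "value": rmse(case.test, case.reference, m)})
        rows.append({"case": case.case_id, "metric": "psnr_db",
                     "value": psnr(case.test, case.reference, m,
                                   max_p=case.max_p)})
        for organ, (ref_c, test_c) in case.contours.items():
            rows.append({"case": case.case_id, "metric": f"dsc_{organ}",
                         "value": dsc(ref_c, test_c)})
            rows.append({"case": case.case_id, "metric": f"mda_{organ}_mm",
                         "value": mda(ref_c, test_c)})
        if case.dose is not None:
            _, rate = gamma_index(case.dose[0], case.dose[1], gamma_cfg)
            rows.append({"case": case.case_id,
                         "metric": "gamma_pass_percent", "value": rate})
    df = pd.DataFrame(rows)
    summary = {}
    for metric, grp in df.groupby("metric", sort=True):
        vals = grp["value"].to_numpy(dtype=float)
        finite = vals[np.isfinite(vals)]
        mean = float(finite.mean()) if len(finite) else float("nan")
        sd = float(finite.std(ddof=1)) if len(finite) > 1 else 0.0
        summary[metric] = {"mean": mean, "sd": sd, "n": int(len(vals))}
    if out_csv is not None:
        Path(out_csv).parent.mkdir(parents=True, exist_ok=True)
        df.to_csv(out_csv, index=False)
    if out_json is not None:
        Path(out_json).parent.mkdir(parents=True, exist_ok=True)
        Path(out_json).write_text(json.dumps(summary, indent=2,
                                             sort_keys=True) + "\n")
    return df, summary
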