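"""Pixel-intensity colocalization: Pearson, Manders, Costes.

Implements the standard two-channel colocalization battery over arbitrary
binary regions of interest:

* Pearson correlation coefficient (PCC) of voxel intensities;
* Manders split coefficients M1/M2 (fraction of one channel's integrated
  intensity falling where the partner channel is above threshold);
* Manders overlap coefficient MOC, the normalized cross product
  sum(ch1*ch2) / sqrt(sum(ch1^2) * sum(ch2^2));
* Costes automatic thresholding: an orthogonal (total-least-squares)
  regression of ch2 on ch1 defines a line t2 = a*t1 + b along which the
  threshold pair is lowered from the intensity maximum until the PCC of the
  voxels below both thresholds drops to <= 0;
* Costes significance testing: PSF-sized blocks of channel 2 are permuted
  within the mask to build a null PCC distribution and a one-sided p-value.

MOC (the overlap coefficient R) and M1/M2 are distinct quantities that travel
under similar names in the literature; both are computed and reported.
"""

from __future__ import annotations

from dataclasses import dataclass
import math

import numpy as np
import pandas as pd

from .image_io import ImageStack, RoiSet

#: Default permutation-block edge, nm: twice a ~120 nm lateral FWHM.
DEFAULT_BLOCK_NM = 240.0


def _masked_pair(ch1, ch2, mask):
    """Congruence-checked flattened intensity vectors under a mask."""
    a1 = ch1.data if isinstance(ch1, ImageStack) else np.asarray(ch1)
    a2 = ch2.data if isinstance(ch2, ImageStack) else np.asarray(ch2)
    if a1.shape != a2.shape:
        raise ValueError(f"channels not congruent: {a1.shape} vs {a2.shape}")
    if mask is None:
        mask = np.ones(a1.shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != a1.shape:
        raise ValueError(f"mask shape {mask.shape} does not match {a1.shape}")
    return a1[mask].astype(np.float64), a2[mask].astype(np.float64), mask


def _pearson_vec(v1: np.ndarray, v2: np.ndarray) -> float:
    v1c = v1 - v1.mean()
    v2c = v2 - v2.mean()
    denom = math.sqrt(float(v1c @ v1c) * float(v2c @ v2c))
    if denom == 0:
        raise ValueError("Pearson r undefined: a channel is constant in the mask")
    return float(v1c @ v2c) / denom


def pearson(ch1, ch2, mask=None) -> float:
    """Pearson correlation of voxel intensities within a mask."""
    v1, v2, _ = _masked_pair(ch1, ch2, mask)
    if v1.size < 2:
        raise ValueError("Pearson r needs at least 2 masked voxels")
    return _pearson_vec(v1, v2)


def manders_split(ch1, ch2, t1: float, t2: float, mask=None) -> tuple[float, float]:
    """Manders split coefficients at a given threshold pair.

    M1 = sum of ch1 over voxels where ch2 > t2, divided by the total ch1 in
    the mask; M2 symmetrically.  The numerator's own channel is not
    thresholded (plain Manders split, co-occurrence defined by the partner
    channel's threshold).
    """
    v1, v2, _ = _masked_pair(ch1, ch2, mask)
    s1 = float(v1.sum())
    s2 = float(v2.sum())
    if s1 == 0 or s2 == 0:
        raise ValueError("Manders split undefined: a channel sums to zero in the mask")
    m1 = float(v1[v2 > t2].sum()) / s1
    m2 = float(v2[v1 > t1].sum()) / s2
    return m1, m2


def manders_overlap(ch1, ch2, mask=None) -> float:
    """Manders overlap coefficient sum(ch1*ch2)/sqrt(sum(ch1^2)*sum(ch2^2))."""
    v1, v2, _ = _masked_pair(ch1, ch2, mask)
    denom = math.sqrt(float(v1 @ v1) * float(v2 @ v2))
    if denom == 0:
        raise ValueError("MOC undefined: a channel is all zero in the mask")
    return float(v1 @ v2) / denom


@dataclass(frozen=True)
class CostesThresholds:
    """Result of the automatic threshold search."""

    t1: float
    t2: float
    slope: float
    intercept: float
    degenerate: bool = False  # scan hit the intensity floor (e.g. ch2 == ch1)


def _tls_line(v1: np.ndarray, v2: np.ndarray) -> tuple[float, float]:
    """Orthogonal (total least squares) regression v2 = a*v1 + b."""
    m1, m2 = v1.mean(), v2.mean()
    cov = np.cov(np.stack([v1, v2]))
    evals, evecs = np.linalg.eigh(cov)
    major = evecs[:, int(np.argmax(evals))]
    if abs(major[0]) < 1e-300:
        raise ValueError("orthogonal regression is vertical; thresholds undefined")
    a = float(major[1] / major[0])
    b = float(m2 - a * m1)
    return a, b


def costes_threshold(ch1, ch2, mask=None) -> CostesThresholds:
    """Automatic threshold pair after Costes.

    Scans t1 downward from max(ch1) along the orthogonal-regression line
    (t2 = a*t1 + b) and returns the highest pair at which the Pearson r of
    the voxels with ch1 < t1 AND ch2 < t2 is <= 0.  Scan step is one
    quantization level for integer data, 1/1000 of the range for floats.
    Perfectly correlated channels never satisfy the stop rule; the scan then
    terminates at the intensity floor and the result is flagged degenerate.
    """
    v1, v2, _ = _masked_pair(ch1, ch2, mask)
    if v1.size < 2 or v1.min() == v1.max() or v2.min() == v2.max():
        raise ValueError("Costes thresholding needs both channels to vary in the mask")
    a, b = _tls_line(v1, v2)
    if a <= 0:
        raise ValueError(
            f"Costes thresholds undefined: regression slope {a:.4g} <= 0 "
            "(anti-correlated channels)"
        )
    lo1, hi1 = float(v1.min()), float(v1.max())
    lo2 = float(v2.min())
    is_int = all(
        np.issubdtype(np.asarray(c.data if isinstance(c, ImageStack) else c).dtype, np.integer)
        for c in (ch1, ch2)
    )
    step = 1.0 if is_int else (hi1 - lo1) / 1000.0
    t1 = hi1
    while t1 >= lo1 - 1e-12 * max(1.0, abs(lo1)):
        t2 = a * t1 + b
        below = (v1 < t1) & (v2 < t2)
        if int(below.sum()) >= 2:
            b1, b2 = v1[below], v2[below]
            if b1.min() != b1.max() and b2.min() != b2.max():
                if _pearson_vec(b1, b2) <= 0:
                    return CostesThresholds(
                        t1=float(t1), t2=float(max(t2, lo2)), slope=a, intercept=b
                    )
        t1 -= step
    return CostesThresholds(
        t1=lo1, t2=float(max(a * lo1 + b, lo2)), slope=a, intercept=b, degenerate=True
    )


@dataclass(frozen=True)
class CostesSignificance:
    """Block-permutation significance of an observed PCC."""

    p_value: float
    r_obs: float
    null_mean: float
    null_sd: float
    n_perm: int
    n_blocks: int


def _complete_blocks(mask: np.ndarray, block_vox: tuple[int, int, int]) -> list[np.ndarray]:
    """Flat voxel-index arrays of the blocks lying fully inside the mask.

    The mask's bounding region is partitioned into fixed blocks anchored at
    the bounding-box origin; blocks not fully inside the mask are frozen
    (never permuted).
    """
    idx = np.nonzero(mask)
    starts = [int(i.min()) for i in idx]
    stops = [int(i.max()) + 1 for i in idx]
    blocks = []
    flat_index = np.arange(mask.size).reshape(mask.shape)
    for z0 in range(starts[0], stops[0], block_vox[0]):
        for y0 in range(starts[1], stops[1], block_vox[1]):
            for x0 in range(starts[2], stops[2], block_vox[2]):
                sl = (
                    slice(z0, z0 + block_vox[0]),
                    slice(y0, y0 + block_vox[1]),
                    slice(x0, x0 + block_vox[2]),
                )
                if (
                    z0 + block_vox[0] <= mask.shape[0]
                    and y0 + block_vox[1] <= mask.shape[1]
                    and x0 + block_vox[2] <= mask.shape[2]
                    and bool(mask[sl].all())
                ):
                    blocks.append(flat_index[sl].ravel())
    return blocks


def costes_significance(
    ch1,
    ch2,
    mask=None,
    block_nm: float = DEFAULT_BLOCK_NM,
    n_perm: int = 199,
    seed: int = 0,
) -> CostesSignificance:
    """Costes randomization test of the observed PCC.

    Channel 2 is scrambled by permuting complete PSF-sized blocks (edge
    ``block_nm``, converted per axis to whole voxels) uniformly among their
    positions inside the mask; partial blocks stay frozen.  One-sided
    p = (1 + #{r_null >= r_obs}) / (n_perm + 1).
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    vs = None
    for c in (ch1, ch2):
        if isinstance(c, ImageStack):
            vs = c.voxel_size
            break
    if vs is None:
        vs = (1.0, 1.0, 1.0)
    if block_nm < max(vs):
        raise ValueError(
            f"block_nm ({block_nm}) must be at least one voxel ({max(vs)} nm)"
        )
    v1, v2, mask = _masked_pair(ch1, ch2, mask)
    block_vox = tuple(max(1, int(round(block_nm / s))) for s in vs)
    blocks = _complete_blocks(mask, block_vox)
    if len(blocks) < 10:
        raise ValueError(
            f"mask too small for block test: {len(blocks)} complete "
            f"{block_vox}-voxel blocks (need >= 10)"
        )
    r_obs = _pearson_vec(v1, v2)

    # map global flat indices to positions in the mask vector
    pos_in_mask = np.full(mask.size, -1, dtype=np.int64)
    pos_in_mask[np.flatnonzero(mask.ravel())] = np.arange(v1.size)
    block_pos = np.stack([pos_in_mask[b] for b in blocks])  # (nblk, bsz)
    assert (block_pos >= 0).all()
    block_vals = v2[block_pos]
    flat_positions = block_pos.ravel()

    rng = np.random.default_rng(seed)
    v1c = v1 - v1.mean()
    n = v1.size
    null = np.empty(n_perm)
    v2p = v2.copy()
    nblk = len(blocks)
    for i in range(n_perm):
        order = rng.permutation(nblk)
        v2p[flat_positions] = block_vals[order].ravel()
        v2c = v2p - v2p.mean()
        denom = math.sqrt(float(v1c @ v1c) * float(v2c @ v2c))
        null[i] = float(v1c @ v2c) / denom if denom > 0 else 0.0
    p = (1.0 + float(np.count_nonzero(null >= r_obs))) / (n_perm + 1.0)
    return CostesSignificance(
        p_value=p,
        r_obs=r_obs,
        null_mean=float(null.mean()),
        null_sd=float(null.std(ddof=1)),
        n_perm=n_perm,
        n_blocks=nblk,
    )


@dataclass
class ColocResult:
    """Full colocalization readout for one region of interest."""

    roi_name: str
    n_voxels: int
    pcc: float
    m1: float
    m2: float
    moc: float
    t1: float
    t2: float
    costes_p: float
    n_perm: int
    note: str = ""


_CSV_COLUMNS = [
    "roi",
    "n_voxels",
    "pcc",
    "m1",
    "m2",
    "moc",
    "t1",
    "t2",
    "costes_p",
    "n_perm",
    "note",
]


def roi_colocalization(
    ch1,
    ch2,
    rois: RoiSet,
    n_perm: int = 199,
    seed: int = 0,
    block_nm: float = DEFAULT_BLOCK_NM,
) -> pd.DataFrame:
    """The full battery over cell, nucleus, nucleolus and extranucleolar ROIs.

    Manders split coefficients are evaluated at the per-ROI Costes thresholds.
    ``n_perm=0`` skips the randomization test (costes_p reported as NaN).
    A ROI whose computation fails (e.g. empty region) yields a row of NaNs
    with the reason in ``note``; the other ROIs are still computed.
    """
    rows = []
    for name, mask in rois.named_masks().items():
        row = {c: np.nan for c in _CSV_COLUMNS}
        row["roi"] = name
        row["n_voxels"] = int(np.count_nonzero(mask))
        row["n_perm"] = n_perm
        row["note"] = ""
        try:
            thr = costes_threshold(ch1, ch2, mask)
            m1, m2 = manders_split(ch1, ch2, thr.t1, thr.t2, mask)
            row.update(
                pcc=pearson(ch1, ch2, mask),
                m1=m1,
                m2=m2,
                moc=manders_overlap(ch1, ch2, mask),
                t1=thr.t1,
                t2=thr.t2,
            )
            if thr.degenerate:
                row["note"] = "degenerate: perfectly correlated"
            if n_perm:
                sig = costes_significance(
                    ch1, ch2, mask, block_nm=block_nm, n_perm=n_perm, seed=seed
                )
                row["costes_p"] = sig.p_value
        except ValueError as exc:
            row["note"] = f"{name}: {exc}"
        rows.append(row)
    return pd.DataFrame(rows, columns=_CSV_COLUMNS)
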