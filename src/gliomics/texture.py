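"""The 41-feature 3D texture catalogue and histogram statistics.

Intensities inside a region of interest are min-max quantized to Ng gray
levels; four texture matrix families are then accumulated over the full 3D
region:

* **GLCM** — symmetric gray-level co-occurrence, merged over all 13 unique
  3D unit offsets at Chebyshev distance 1 (10 features);
* **GLRLM** — gray-level run-length, merged over the same 13 directions
  (13 features);
* **GLSZM** — gray-level size-zone with 26-connected zones (13 features);
* **NGTDM** — neighborhood gray-tone difference over the 26-neighborhood
  (5 features).

Formulas follow the standard radiomics definitions of each named feature.
Six histogram statistics (mean, variance, skewness, kurtosis, energy,
entropy) complete the first-order description; entropy and energy use a
64-bin equal-width histogram and base-2 logarithms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage


#: The 13 unique 3D offsets at Chebyshev distance 1 (half of the 26-neighborhood).
OFFSETS_3D = tuple(
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) > (0, 0, 0)
)

GLCM_FEATURES = (
    "energy", "contrast", "correlation", "entropy", "inverse_difference_moment",
    "variance", "sum_average", "dissimilarity", "imc1", "imc2",
)
GLRLM_FEATURES = (
    "sre", "lre", "gln", "rln", "rp", "lgre", "hgre",
    "srlge", "srhge", "lrlge", "lrhge", "glv", "rlv",
)
GLSZM_FEATURES = (
    "sze", "lze", "gln", "zsn", "zp", "lgze", "hgze",
    "szlge", "szhge", "lzlge", "lzhge", "glv", "zsv",
)
NGTDM_FEATURES = ("coarseness", "contrast", "busyness", "complexity", "strength")

HISTOGRAM_FEATURES = ("mean", "variance", "skewness", "kurtosis", "energy", "entropy")

#: (family, feature) pairs of the 41-feature texture catalogue.
TEXTURE_CATALOGUE = (
    tuple(("glcm", f) for f in GLCM_FEATURES)
    + tuple(("glrlm", f) for f in GLRLM_FEATURES)
    + tuple(("glszm", f) for f in GLSZM_FEATURES)
    + tuple(("ngtdm", f) for f in NGTDM_FEATURES)
)
assert len(TEXTURE_CATALOGUE) == 41


@dataclass
class QuantizedROI:
    """Gray levels 1..Ng inside the mask, 0 outside."""

    levels: np.ndarray
    Ng: int
    source: str = ""
    degenerate: bool = False


def quantize_roi(volume: np.ndarray, mask: np.ndarray, Ng: int = 32, source: str = "") -> QuantizedROI:
    """Equal-width min-max quantization of in-mask intensities to 1..Ng.

    The in-mask minimum maps to level 1 and the maximum to Ng, making all
    downstream texture features invariant under affine intensity transforms.
    A constant ROI yields all-ones with the degenerate flag set.
    """
    mask = np.asarray(mask).astype(bool)
    if Ng < 2:
        raise ValueError("Ng must be >= 2")
    if not mask.any():
        raise ValueError("empty mask")
    vals = np.asarray(volume, dtype=float)[mask]
    lo, hi = vals.min(), vals.max()
    levels = np.zeros(mask.shape, dtype=np.int32)
    if hi <= lo:
        levels[mask] = 1
        return QuantizedROI(levels, Ng, source, degenerate=True)
    q = np.floor((np.asarray(volume, dtype=float) - lo) / (hi - lo) * Ng).astype(np.int32) + 1
    q = np.clip(q, 1, Ng)
    levels[mask] = q[mask]
    return QuantizedROI(levels, Ng, source)


# ---------------------------------------------------------------------------
# texture matrices


@dataclass
class TextureMatrixSet:
    """GLCM, GLRLM, GLSZM and NGTDM accumulated over one quantized ROI."""

    glcm: np.ndarray        # Ng x Ng, normalized, symmetric
    glrlm: np.ndarray       # Ng x max-run-length counts
    glszm: np.ndarray       # Ng x max-zone-size counts
    ngtdm_s: np.ndarray     # per-level summed absolute neighborhood differences
    ngtdm_n: np.ndarray     # per-level voxel counts
    Ng: int
    degenerate: bool = False


def _glcm(levels: np.ndarray, mask: np.ndarray, Ng: int) -> np.ndarray:
    counts = np.zeros((Ng, Ng), dtype=np.int64)
    for off in OFFSETS_3D:
        src = tuple(slice(max(-o, 0), s - max(o, 0)) for o, s in zip(off, levels.shape))
        dst = tuple(slice(max(o, 0), s - max(-o, 0)) for o, s in zip(off, levels.shape))
        a, b = levels[src], levels[dst]
        valid = mask[src] & mask[dst]
        np.add.at(counts, (a[valid] - 1, b[valid] - 1), 1)
    counts = counts + counts.T  # symmetric pairing
    total = counts.sum()
    return counts / total if total else counts.astype(float)


def _shifted(a: np.ndarray, off: tuple[int, int, int]) -> np.ndarray:
    """Array aligned so that shifted(a)[p] = a[p + off], zero out of bounds."""
    out = np.zeros_like(a)
    src = tuple(slice(max(o, 0), s + min(o, 0)) for o, s in zip(off, a.shape))
    dst = tuple(slice(max(-o, 0), s + min(-o, 0)) for o, s in zip(off, a.shape))
    out[dst] = a[src]
    return out


def _glrlm(levels: np.ndarray, mask: np.ndarray, Ng: int) -> np.ndarray:
    """Run-length counts merged over the 13 directions.

    A run is a maximal sequence of equal gray levels along a direction,
    fully inside the mask.  Suffix run lengths satisfy
    L[p] = 1 + L[p + off] if the run continues at p, which is solved by
    iterating shifted updates until a fixed point (bounded by the longest
    run).
    """
    lab = np.where(mask, levels, 0)
    max_len = max(levels.shape)
    counts = np.zeros((Ng, max_len), dtype=np.int64)
    for off in OFFSETS_3D:
        nxt = _shifted(lab, off)
        prv = _shifted(lab, tuple(-o for o in off))
        starts = (lab > 0) & (prv != lab)
        cont = (lab > 0) & (nxt == lab)
        length = (lab > 0).astype(np.int32)
        while True:
            upd = 1 + np.where(cont, _shifted(length, off), 0)
            upd[lab == 0] = 0
            if np.array_equal(upd, length):
                break
            length = upd
        lv = lab[starts] - 1
        ln = length[starts] - 1
        np.add.at(counts, (lv, ln), 1)
    return counts


def _glszm(levels: np.ndarray, mask: np.ndarray, Ng: int) -> np.ndarray:
    lab = np.where(mask, levels, 0)
    n_vox = int(mask.sum())
    counts = np.zeros((Ng, max(n_vox, 1)), dtype=np.int64)
    structure = np.ones((3, 3, 3), dtype=bool)  # 26-connectivity
    for g in np.unique(lab[lab > 0]):
        comp, n = ndimage.label(lab == g, structure=structure)
        if n:
            sizes = np.bincount(comp.ravel())[1:]
            for s in sizes:
                counts[g - 1, s - 1] += 1
    return counts


def _ngtdm(levels: np.ndarray, mask: np.ndarray, Ng: int) -> tuple[np.ndarray, np.ndarray]:
    lab = np.where(mask, levels, 0).astype(float)
    kernel = np.ones((3, 3, 3))
    kernel[1, 1, 1] = 0.0
    neighbor_sum = ndimage.convolve(lab, kernel, mode="constant", cval=0.0)
    neighbor_cnt = ndimage.convolve(mask.astype(float), kernel, mode="constant", cval=0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_nb = neighbor_sum / neighbor_cnt
    valid = mask & (neighbor_cnt > 0)
    s = np.zeros(Ng)
    n = np.zeros(Ng, dtype=np.int64)
    lv = levels[valid]
    diff = np.abs(levels[valid].astype(float) - mean_nb[valid])
    np.add.at(s, lv - 1, diff)
    np.add.at(n, lv - 1, 1)
    return s, n


def compute_texture_matrices(q: QuantizedROI) -> TextureMatrixSet:
    """Accumulate all four texture matrices over the quantized ROI.

    Out-of-mask neighbors are excluded from all pair/run/zone/neighborhood
    counts.  A single-voxel ROI has no pairs; the degenerate flag is set and
    downstream features fall back to defined values.
    """
    mask = q.levels > 0
    if mask.any():  # crop to the mask bounding box; counts are unaffected
        idx = np.nonzero(mask)
        sl = tuple(slice(int(i.min()), int(i.max()) + 1) for i in idx)
        levels = q.levels[sl]
        mask = mask[sl]
    else:
        levels = q.levels
    q = QuantizedROI(levels, q.Ng, q.source, q.degenerate)
    glcm = _glcm(q.levels, mask, q.Ng)
    glrlm = _glrlm(q.levels, mask, q.Ng)
    glszm = _glszm(q.levels, mask, q.Ng)
    s, n = _ngtdm(q.levels, mask, q.Ng)
    degenerate = q.degenerate or glcm.sum() == 0
    return TextureMatrixSet(glcm, glrlm, glszm, s, n, q.Ng, degenerate)


# ---------------------------------------------------------------------------
# features


def _glcm_features(p: np.ndarray) -> dict[str, float]:
    Ng = p.shape[0]
    i = np.arange(1, Ng + 1, dtype=float)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)
    mu = (i * px).sum()
    var = ((i - mu) ** 2 * px).sum()
    nz = p > 0
    ent = -(p[nz] * np.log2(p[nz])).sum()
    feats = {
        "energy": float((p**2).sum()),
        "contrast": float(((ii - jj) ** 2 * p).sum()),
        "entropy": float(ent),
        "inverse_difference_moment": float((p / (1.0 + (ii - jj) ** 2)).sum()),
        "variance": float(var),
        "sum_average": float(((ii + jj) * p).sum() / 2.0),
        "dissimilarity": float((np.abs(ii - jj) * p).sum()),
    }
    if var > 0:
        cov = (((ii - mu) * (jj - mu)) * p).sum()
        feats["correlation"] = float(cov / var)
        # information measures of correlation (symmetric p: HX == HY)
        pxj = np.outer(px, px)
        both = (p > 0) & (pxj > 0)
        hxy = ent
        hxy1 = -(p[both] * np.log2(pxj[both])).sum()
        hxy2 = -(pxj[both] * np.log2(pxj[both])).sum()
        hx = -(px[px > 0] * np.log2(px[px > 0])).sum()
        feats["imc1"] = float((hxy - hxy1) / hx) if hx > 0 else 0.0
        arg = 1.0 - np.exp(-2.0 * (hxy2 - hxy))
        feats["imc2"] = float(np.sqrt(max(arg, 0.0)))
    else:
        feats["correlation"] = 0.0
        feats["imc1"] = 0.0
        feats["imc2"] = 0.0
    return feats


def _run_zone_features(counts: np.ndarray, names: tuple[str, ...]) -> dict[str, float]:
    """The 13 shared gray-level / run-length (or zone-size) statistics."""
    total = counts.sum()
    if total == 0:
        return {k: 0.0 for k in names}
    p = counts / total
    Ng, Nr = p.shape
    g = np.arange(1, Ng + 1, dtype=float)[:, None]
    r = np.arange(1, Nr + 1, dtype=float)[None, :]
    pg = p.sum(axis=1)
    pr = p.sum(axis=0)
    n_vox = (counts * r).sum()
    mu_g = (p * g).sum()
    mu_r = (p * r).sum()
    vals = (
        float((p / r**2).sum()),                   # SRE / SZE
        float((p * r**2).sum()),                   # LRE / LZE
        float((pg**2).sum() * total),              # GLN
        float((pr**2).sum() * total),              # RLN / ZSN
        float(total / n_vox) if n_vox else 0.0,    # RP / ZP
        float((p / g**2).sum()),                   # LGRE / LGZE
        float((p * g**2).sum()),                   # HGRE / HGZE
        float((p / (g**2 * r**2)).sum()),          # SRLGE / SZLGE
        float((p * g**2 / r**2).sum()),            # SRHGE / SZHGE
        float((p * r**2 / g**2).sum()),            # LRLGE / LZLGE
        float((p * g**2 * r**2).sum()),            # LRHGE / LZHGE
        float((p * (g - mu_g) ** 2).sum()),        # GLV
        float((p * (r - mu_r) ** 2).sum()),        # RLV / ZSV
    )
    return dict(zip(names, vals))


def _ngtdm_features(s: np.ndarray, n: np.ndarray) -> dict[str, float]:
    Ng = len(n)
    n_tot = n.sum()
    if n_tot == 0:
        return {k: 0.0 for k in NGTDM_FEATURES}
    p = n / n_tot
    i = np.arange(1, Ng + 1, dtype=float)
    present = n > 0
    n_p = int(present.sum())
    eps = np.finfo(float).eps
    coarseness = 1.0 / max((p * s).sum(), eps)
    if n_p > 1:
        ii, jj = np.meshgrid(i, i, indexing="ij")
        pi, pj = np.meshgrid(p, p, indexing="ij")
        both = np.outer(present, present)
        contrast = (
            (pi * pj * (ii - jj) ** 2)[both].sum() / (n_p * (n_p - 1))
        ) * (s.sum() / n_tot)
        busyness_den = np.abs(i[present, None] * p[present, None] - i[None, present] * p[None, present]).sum()
        busyness = (p * s).sum() / busyness_den if busyness_den > 0 else 0.0
        with np.errstate(divide="ignore", invalid="ignore"):
            comp_terms = np.abs(ii - jj) / (n_tot * (pi + pj)) * (pi * s[:, None] + pj * s[None, :])
        complexity = float(comp_terms[both & ((pi + pj) > 0)].sum())
        strength_num = ((pi + pj) * (ii - jj) ** 2)[both].sum()
        strength = strength_num / max(s.sum(), eps)
    else:
        contrast = 0.0
        busyness = 0.0
        complexity = 0.0
        strength = 0.0
    return {
        "coarseness": float(coarseness),
        "contrast": float(contrast),
        "busyness": float(busyness),
        "complexity": float(complexity),
        "strength": float(strength),
    }


def texture_feature_vector(m: TextureMatrixSet) -> dict[str, float]:
    """The 41 named texture features, keyed ``<family>.<feature>``.

    Zero-variance GLCMs set correlation and both information measures of
    correlation to 0 (degenerate convention); all values are finite.
    """
    out = {}
    for k, v in _glcm_features(m.glcm).items():
        out[f"glcm.{k}"] = v
    for k, v in _run_zone_features(m.glrlm, GLRLM_FEATURES).items():
        out[f"glrlm.{k}"] = v
    for k, v in _run_zone_features(m.glszm, GLSZM_FEATURES).items():
        out[f"glszm.{k}"] = v
    for k, v in _ngtdm_features(m.ngtdm_s, m.ngtdm_n).items():
        out[f"ngtdm.{k}"] = v
    assert len(out) == 41
    return out


# ---------------------------------------------------------------------------
# histogram statistics


def histogram_stats(volume: np.ndarray, mask: np.ndarray, bins: int = 64) -> dict[str, float]:
    """Mean, variance, skewness, kurtosis (standardized 3rd/4th central
    moments; kurtosis of a Gaussian is 3), histogram energy Σp² and entropy
    −Σp log2 p over ``bins`` equal-width bins of the in-mask intensities.

    A constant ROI returns variance 0 and skewness/kurtosis 0 by convention.
    """
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise ValueError("empty mask")
    x = np.asarray(volume, dtype=float)[mask]
    mean = float(x.mean())
    var = float(x.var())
    if var > 0:
        z = (x - mean) / np.sqrt(var)
        skew = float((z**3).mean())
        kurt = float((z**4).mean())
    else:
        skew = 0.0
        kurt = 0.0
    counts, _ = np.histogram(x, bins=bins)
    p = counts[counts > 0] / x.size
    energy = float((p**2).sum())
    entropy = float(-(p * np.log2(p)).sum())
    return {
        "mean": mean,
        "variance": var,
        "skewness": skew,
        "kurtosis": kurt,
        "energy": energy,
        "entropy": entropy,
    }
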