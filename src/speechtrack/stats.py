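"""Group-level inference on source maps.

Voxelwise pseudo-t statistics (the variance map is Gaussian-smoothed at
15 mm FWHM before forming t, suppressing high-spatial-frequency noise),
threshold-free cluster enhancement (TFCE), and family-wise error
control by the permutation maximum statistic — group-label shuffling
for independent designs, within-subject condition swaps (sign flips of
the paired differences) for dependent designs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import numpy as np
from scipy import ndimage

from .beamformer import SourceMap
from .forward import SourceGrid


@dataclass
class StatMap:
    t_values: np.ndarray
    df: int
    design: str  # "independent" | "dependent"
    smoothing_fwhm_mm: float
    grid: SourceGrid | None = None


@dataclass
class TfceParams:
    """TFCE settings: TFCE(v) = sum_h e_v(h)^E * h^H * dh.

    ``dh=None`` means max|t| / ``n_steps`` at call time (coarser steps
    trade integration accuracy for speed and leave the permutation
    ranking essentially unchanged); ``connectivity`` is the 3-D
    neighborhood (6, 18 or 26).
    """

    E: float = 0.5
    H: float = 2.0
    dh: float | None = None
    n_steps: int = 100
    connectivity: int = 26


@dataclass
class PermutationResult:
    n_perms: int
    max_stat_null: np.ndarray
    fwe_p: np.ndarray
    scheme: str
    seed: int
    observed_tfce: np.ndarray | None = None
    observed_t: np.ndarray | None = None


def _stack(maps) -> np.ndarray:
    if isinstance(maps, np.ndarray):
        return np.atleast_2d(maps)
    return np.stack([m.values if isinstance(m, SourceMap) else np.asarray(m)
                     for m in maps])


def _grid_of(maps, grid):
    if grid is not None:
        return grid
    for m in maps:
        if isinstance(m, SourceMap):
            return m.grid
    raise ValueError("a SourceGrid is required (pass grid= or SourceMap inputs)")


def _smooth_masked(values: np.ndarray, grid: SourceGrid, fwhm_mm: float) -> np.ndarray:
    """Gaussian smoothing of a masked-grid scalar field, mask-normalized."""
    if fwhm_mm <= 0:
        return values
    shape, idx = grid.shape3d()
    vol = np.zeros(shape)
    msk = np.zeros(shape)
    mi = idx[grid.inside_mask]
    vol[mi[:, 0], mi[:, 1], mi[:, 2]] = values
    msk[mi[:, 0], mi[:, 1], mi[:, 2]] = 1.0
    sigma_vox = (fwhm_mm / 1000.0) / (2.0 * np.sqrt(2 * np.log(2))) / grid.spacing
    num = ndimage.gaussian_filter(vol, sigma_vox)
    den = ndimage.gaussian_filter(msk, sigma_vox)
    out = np.where(den > 1e-12, num / np.where(den > 0, den, 1.0), 0.0)
    return out[mi[:, 0], mi[:, 1], mi[:, 2]]


def pseudo_t_map(maps_a, maps_b, design: str = "independent",
                 fwhm_mm: float = 15.0, grid: SourceGrid | None = None) -> StatMap:
    """Voxelwise (pseudo-)t contrast between two sets of subject maps.

    Independent: two-sample t with pooled variance; dependent: paired t
    on within-subject differences. With ``fwhm_mm > 0`` the variance map
    is smoothed before forming t; ``fwhm_mm = 0`` recovers the ordinary
    t statistic. Voxels with zero smoothed variance are returned as 0.
    """
    A, B = _stack(maps_a), _stack(maps_b)
    g = _grid_of(list(maps_a) + list(maps_b), grid)
    if design == "dependent":
        if A.shape != B.shape:
            raise ValueError("paired design requires equal subject counts")
        d = A - B
        n = d.shape[0]
        if n < 2:
            raise ValueError("need >= 2 subjects")
        v = d.var(axis=0, ddof=1)
        v = _smooth_masked(v, g, fwhm_mm)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = d.mean(axis=0) / np.sqrt(v / n)
        df = n - 1
    elif design == "independent":
        na, nb = A.shape[0], B.shape[0]
        if na < 2 or nb < 2:
            raise ValueError("need >= 2 subjects per group")
        vp = ((na - 1) * A.var(axis=0, ddof=1) + (nb - 1) * B.var(axis=0, ddof=1)) / (na + nb - 2)
        vp = _smooth_masked(vp, g, fwhm_mm)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = (A.mean(axis=0) - B.mean(axis=0)) / np.sqrt(vp * (1 / na + 1 / nb))
        df = na + nb - 2
    else:
        raise ValueError(f"unknown design {design!r}")
    t = np.where(np.isfinite(t), t, 0.0)
    return StatMap(t_values=t, df=df, design=design, smoothing_fwhm_mm=fwhm_mm, grid=g)


def _structure(connectivity: int) -> np.ndarray:
    rank = {6: 1, 18: 2, 26: 3}.get(connectivity)
    if rank is None:
        raise ValueError("connectivity must be 6, 18 or 26")
    return ndimage.generate_binary_structure(3, rank)


def _tfce_one_sign(vol: np.ndarray, mask: np.ndarray, params: TfceParams,
                   dh: float) -> np.ndarray:
    out = np.zeros_like(vol)
    struct = _structure(params.connectivity)
    vmax = vol[mask].max() if mask.any() else 0.0
    h = dh
    while h <= vmax + 1e-12:
        supra = (vol >= h) & mask
        if not supra.any():
            break
        labels, n_lab = ndimage.label(supra, structure=struct)
        sizes = np.bincount(labels.ravel())
        out[supra] += sizes[labels[supra]] ** params.E * h ** params.H * dh
        h += dh
    return out


def tfce(stat: StatMap | np.ndarray, params: TfceParams | None = None,
         grid: SourceGrid | None = None) -> SourceMap:
    """Threshold-free cluster enhancement of a statistic map.

    Sums e(h)^E * h^H * dh over thresholds h up to each voxel's value,
    where e(h) is the voxel count of the connected component containing
    the voxel at threshold h. Negative values are enhanced on the
    negated map and re-negated, so output signs follow input signs.
    """
    params = params or TfceParams()
    if isinstance(stat, StatMap):
        values, g = stat.t_values, stat.grid if grid is None else grid
    else:
        values, g = np.asarray(stat, dtype=float), grid
    if g is None:
        raise ValueError("a SourceGrid is required")
    shape, idx = g.shape3d()
    mi = idx[g.inside_mask]
    vol = np.zeros(shape)
    msk = np.zeros(shape, dtype=bool)
    vol[mi[:, 0], mi[:, 1], mi[:, 2]] = values
    msk[mi[:, 0], mi[:, 1], mi[:, 2]] = True

    dh = params.dh
    if dh is None:
        peak = np.max(np.abs(values)) if values.size else 0.0
        if peak == 0:
            return SourceMap(values=np.zeros_like(values), grid=g, band_label="tfce")
        dh = peak / params.n_steps
    enh = _tfce_one_sign(vol, msk, params, dh) - _tfce_one_sign(-vol, msk, params, dh)
    return SourceMap(values=enh[mi[:, 0], mi[:, 1], mi[:, 2]], grid=g,
                     band_label="tfce")


def _dependent_perms(n: int, n_perms: int, rng) -> np.ndarray:
    """Sign-flip matrix (n_perms x n), enumerating all 2^n flips if few."""
    if 2 ** n <= n_perms:
        warnings.warn(f"only {2 ** n} distinct sign flips; enumerating all")
        bits = np.arange(2 ** n)
        return 1 - 2 * ((bits[:, None] >> np.arange(n)) & 1)
    return rng.choice([-1.0, 1.0], size=(n_perms, n))


def _independent_perms(na: int, nb: int, n_perms: int, rng) -> np.ndarray:
    """Permuted index arrays (n_perms x (na+nb)); group A = first na."""
    n = na + nb
    if comb(n, na) <= n_perms:
        warnings.warn(f"only {comb(n, na)} distinct group splits; enumerating all")
        perms = []
        for ca in combinations(range(n), na):
            rest = [i for i in range(n) if i not in ca]
            perms.append(list(ca) + rest)
        return np.array(perms)
    return np.array([rng.permutation(n) for _ in range(n_perms)])


def permutation_fwe(maps_a, maps_b, design: str = "independent",
                    params: TfceParams | None = None, n_perms: int = 1000,
                    seed: int = 0, fwhm_mm: float = 15.0,
                    grid: SourceGrid | None = None,
                    mask: np.ndarray | None = None) -> PermutationResult:
    """Max-statistic permutation FWE correction of the TFCE map.

    The observed pseudo-t map is TFCE-enhanced; each permutation
    (group-label shuffle or within-subject condition swap) yields a
    permuted map whose maximum |TFCE| (within ``mask`` if given) enters
    the null distribution. fwe_p(v) = (1 + #{null >= |obs(v)|}) /
    (1 + n_perms). Deterministic given ``seed``.
    """
    if n_perms < 100:
        raise ValueError("n_perms must be >= 100")
    params = params or TfceParams()
    rng = np.random.default_rng(seed)
    A, B = _stack(maps_a), _stack(maps_b)
    g = _grid_of(list(maps_a) + list(maps_b), grid)
    vox_mask = np.ones(A.shape[1], dtype=bool) if mask is None else np.asarray(mask, bool)

    obs_stat = pseudo_t_map(A, B, design=design, fwhm_mm=fwhm_mm, grid=g)
    obs_tfce = tfce(obs_stat, params).values
    # freeze dh across permutations so enhanced values are comparable
    dh = params.dh
    if dh is None:
        peak = np.max(np.abs(obs_stat.t_values))
        dh = peak / params.n_steps if peak > 0 else 1.0
    frozen = TfceParams(E=params.E, H=params.H, dh=dh,
                        connectivity=params.connectivity)

    if design == "dependent":
        D = A - B
        signs = _dependent_perms(D.shape[0], n_perms, rng)
        null = np.empty(signs.shape[0])
        zero = np.zeros_like(D)
        for p, s in enumerate(signs):
            t = pseudo_t_map(D * s[:, None], zero, design="dependent",
                             fwhm_mm=fwhm_mm, grid=g)
            null[p] = np.max(np.abs(tfce(t, frozen).values[vox_mask]))
        scheme = "within-subject-swap"
    elif design == "independent":
        stacked = np.concatenate([A, B], axis=0)
        na = A.shape[0]
        perms = _independent_perms(na, B.shape[0], n_perms, rng)
        null = np.empty(perms.shape[0])
        for p, order in enumerate(perms):
            t = pseudo_t_map(stacked[order[:na]], stacked[order[na:]],
                             design="independent", fwhm_mm=fwhm_mm, grid=g)
            null[p] = np.max(np.abs(tfce(t, frozen).values[vox_mask]))
        scheme = "group-shuffle"
    else:
        raise ValueError(f"unknown design {design!r}")

    n_eff = len(null)
    fwe_p = (1 + (null[None, :] >= np.abs(obs_tfce)[:, None]).sum(axis=1)) / (1 + n_eff)
    fwe_p = np.where(vox_mask, fwe_p, 1.0)
    return PermutationResult(n_perms=n_eff, max_stat_null=null, fwe_p=fwe_p,
                             scheme=scheme, seed=seed, observed_tfce=obs_tfce,
                             observed_t=obs_stat.t_values)


def peak_voxel(res: PermutationResult) -> int:
    """Index of the most significant voxel: minimal FWE p, with ties
    (the permutation floor 1/(1+n_perms)) broken by |observed TFCE|."""
    at_min = res.fwe_p == res.fwe_p.min()
    scores = np.where(at_min, np.abs(res.observed_tfce), -np.inf)
    return int(np.argmax(scores))


def interaction_contrast(nat_a, ctrl_a, nat_b, ctrl_b) -> tuple[np.ndarray, np.ndarray]:
    """Per-subject (nat - ctrl) difference maps for both groups.

    The interaction [(nat_A - ctrl_A) - (nat_B - ctrl_B)] is then tested
    as an independent-design group comparison of the differences via
    ``permutation_fwe``.
    """
    NA, CA = _stack(nat_a), _stack(ctrl_a)
    NB, CB = _stack(nat_b), _stack(ctrl_b)
    if NA.shape != CA.shape or NB.shape != CB.shape:
        raise ValueError("each subject needs both condition maps")
    return NA - CA, NB - CB


def sphere_mask(grid: SourceGrid, centers, radius_m: float = 0.010) -> np.ndarray:
    """Small-volume mask: union of spheres around listed coordinates,
    over masked grid points (analogue of a priori ROI spheres)."""
    pts = grid.masked_points
    m = np.zeros(len(pts), dtype=bool)
    for c in np.atleast_2d(np.asarray(centers, dtype=float)):
        m |= np.linalg.norm(pts - c, axis=1) <= radius_m
    return m
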