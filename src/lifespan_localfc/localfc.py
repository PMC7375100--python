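"""Voxelwise local functional connectivity statistics: lFCD and FOCA.

lFCD (local functional connectivity density) counts, for each seed voxel, the
voxels in the contiguous cluster grown from the seed whose time courses
correlate with it above a threshold (default r > 0.6, strict). It is a local
functional-hub measure in the tradition of seed-growing functional
connectivity density mapping.

FOCA (four-dimensional spatial-temporal consistency of local neural activity)
scores each voxel by combining (i) the temporal homogeneity of its cubic
neighborhood — the mean pairwise Pearson correlation among the member time
courses — and (ii) the stability of the neighborhood's spatial pattern between
consecutive time points — the mean Pearson correlation of the pattern at t
with the pattern at t+1. The two components are averaged arithmetically by
default.

Both maps are normalized by their whole-brain (in-mask) mean before group
analysis.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from itertools import product

import nibabel as nib
import numpy as np
from scipy.ndimage import uniform_filter

from .preprocess import VolumeSeries

__all__ = [
    "LocalFCMap",
    "NeighborhoodScheme",
    "tsnr_mask",
    "lfcd_map",
    "foca_map",
    "normalize_map",
]


@dataclass
class NeighborhoodScheme:
    """Spatial neighborhood conventions for the local statistics.

    ``connectivity`` (6, 18 or 26) governs lFCD cluster growth adjacency;
    ``foca_cube`` is the odd edge length (voxels) of the FOCA neighborhood,
    clipped (not padded) at mask and volume edges.
    """

    connectivity: int = 26
    foca_cube: int = 3

    def __post_init__(self) -> None:
        if self.connectivity not in (6, 18, 26):
            raise ValueError("connectivity must be 6, 18 or 26")
        if self.foca_cube < 3 or self.foca_cube % 2 == 0:
            raise ValueError("foca_cube must be odd and >= 3")

    def offsets(self) -> np.ndarray:
        """Adjacency offsets for cluster growth, shape (connectivity, 3)."""
        offs = [
            (dx, dy, dz)
            for dx, dy, dz in product((-1, 0, 1), repeat=3)
            if (dx, dy, dz) != (0, 0, 0)
        ]
        if self.connectivity == 6:
            offs = [o for o in offs if sum(map(abs, o)) == 1]
        elif self.connectivity == 18:
            offs = [o for o in offs if sum(map(abs, o)) <= 2]
        return np.array(offs, dtype=np.intp)


@dataclass
class LocalFCMap:
    """A subject's 3D local-connectivity statistic map with provenance."""

    values: np.ndarray
    statistic: str  # "lfcd" | "foca"
    mask: np.ndarray  # voxels the statistic was computed on
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    corr_threshold: float | None = None
    snr_threshold: float | None = None
    normalized: bool = False
    smoothed_fwhm: float | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != self.mask.shape:
            raise ValueError("values and mask shapes differ")

    def to_nifti(self) -> nib.Nifti1Image:
        return nib.Nifti1Image(self.values.astype(np.float32), self.affine)

    def sidecar(self) -> dict:
        return {
            "statistic": self.statistic,
            "corr_threshold": self.corr_threshold,
            "snr_threshold": self.snr_threshold,
            "normalized": self.normalized,
            "smoothed_fwhm": self.smoothed_fwhm,
        }

    def save(self, path) -> None:
        """Write the map as NIfTI plus a JSON provenance sidecar."""
        nib.save(self.to_nifti(), str(path))
        sidecar_path = str(path)
        for ext in (".nii.gz", ".nii"):
            if sidecar_path.endswith(ext):
                sidecar_path = sidecar_path[: -len(ext)]
                break
        with open(sidecar_path + ".json", "w") as fh:
            json.dump(self.sidecar(), fh, indent=2)


def tsnr_mask(v: VolumeSeries, snr_threshold: float = 50.0) -> np.ndarray:
    """Temporal-SNR gate: keep in-mask voxels with mean/SD >= threshold.

    tSNR is evaluated on the series before nuisance residualization (which
    destroys the mean); callers pass the detrended-but-not-residualized
    series. Constant positive voxels (SD = 0) count as infinite SNR.
    """
    mean = v.data.mean(axis=-1)
    sd = v.data.std(axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        snr = np.where(sd > 0, mean / np.where(sd > 0, sd, 1.0), np.where(mean > 0, np.inf, -np.inf))
    return v.mask & (snr >= snr_threshold)


def _normalized_timeseries(data: np.ndarray, incl: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Zero-mean, unit-norm time courses for included voxels; degenerate
    (zero temporal variance) voxels are removed from ``incl``."""
    t = data.shape[-1]
    flat = data.reshape(-1, t)
    inc = incl.ravel().copy()
    z = np.zeros_like(flat)
    sel = flat[inc]
    centered = sel - sel.mean(axis=1, keepdims=True, dtype=flat.dtype)
    norms = np.linalg.norm(centered, axis=1).astype(flat.dtype)
    good = norms > 0
    idx = np.flatnonzero(inc)
    z[idx[good]] = centered[good] / norms[good, None]
    inc[idx[~good]] = False
    return z, inc.reshape(incl.shape)


def _neighbor_index_table(shape: tuple[int, int, int], offsets: np.ndarray) -> np.ndarray:
    """Flat neighbor indices per voxel, -1 where the offset leaves the grid."""
    nx, ny, nz = shape
    ii, jj, kk = np.indices(shape)
    table = np.full((nx * ny * nz, len(offsets)), -1, dtype=np.intp)
    for a, (dx, dy, dz) in enumerate(offsets):
        ni, nj, nk = ii + dx, jj + dy, kk + dz
        ok = (ni >= 0) & (ni < nx) & (nj >= 0) & (nj < ny) & (nk >= 0) & (nk < nz)
        flat = (ni * ny + nj) * nz + nk
        table[:, a] = np.where(ok, flat, -1).ravel()
    return table


def lfcd_map(
    v: VolumeSeries,
    scheme: NeighborhoodScheme | None = None,
    r_threshold: float = 0.6,
    snr: np.ndarray | None = None,
    mode: str = "seed_corr",
) -> LocalFCMap:
    """Local functional connectivity density by seed-growing cluster search.

    For each included voxel s, a cluster is grown breadth-first: any included
    voxel adjacent (per ``scheme.connectivity``) to a current member joins the
    cluster when its Pearson correlation with the *seed's* time course is
    strictly greater than ``r_threshold``. The raw lFCD value is the final
    cluster cardinality (seed included, so the minimum on an included voxel
    is 1); excluded voxels get 0.

    ``mode="chain_corr"`` instead links neighboring voxel pairs whose mutual
    correlation exceeds the threshold and assigns each voxel the size of its
    connected component in that graph.
    """
    if scheme is None:
        scheme = NeighborhoodScheme()
    if not (0.0 < r_threshold < 1.0):
        raise ValueError("r_threshold must be in (0, 1)")
    if mode not in ("seed_corr", "chain_corr"):
        raise ValueError(f"unknown lFCD mode {mode!r}")
    if v.n_timepoints < 3:
        raise ValueError("correlation undefined for fewer than 3 timepoints")

    incl = v.mask if snr is None else (v.mask & np.asarray(snr, dtype=bool))
    shape = v.data.shape[:3]
    z, incl = _normalized_timeseries(v.data, incl)
    inc_flat = incl.ravel()
    offsets = scheme.offsets()
    table = _neighbor_index_table(shape, offsets)

    # neighbor-pair correlations, one volume per offset; a seed enters the
    # BFS only if at least one immediate neighbor already exceeds the
    # threshold, which is also the first BFS ring in seed_corr mode
    n_vox = z.shape[0]
    exceed = np.zeros((n_vox, len(offsets)), dtype=bool)
    for a in range(len(offsets)):
        nb = table[:, a]
        ok = (nb >= 0) & inc_flat & inc_flat[np.clip(nb, 0, None)]
        rows = np.flatnonzero(ok)
        if rows.size:
            corr = np.einsum("ij,ij->i", z[rows], z[nb[rows]])
            exceed[rows, a] = corr > r_threshold

    values = np.zeros(n_vox, dtype=np.float64)
    values[inc_flat] = 1.0
    has_link = exceed.any(axis=1)

    if mode == "chain_corr":
        values[inc_flat & has_link] = 0.0  # filled by component sizes below
        comp = _chain_components(table, exceed, inc_flat)
        for members in comp:
            values[members] = len(members)
    else:
        visited = np.zeros(n_vox, dtype=bool)
        for seed in np.flatnonzero(inc_flat & has_link):
            zs = z[seed]
            cluster_size = 1
            visited[seed] = True
            touched = [seed]
            frontier = np.array([seed], dtype=np.intp)
            while frontier.size:
                cand = table[frontier].ravel()
                cand = cand[cand >= 0]
                cand = cand[inc_flat[cand] & ~visited[cand]]
                if cand.size == 0:
                    break
                cand = np.unique(cand)
                visited[cand] = True
                touched.extend(cand.tolist())
                corr = z[cand] @ zs
                accepted = cand[corr > r_threshold]
                cluster_size += accepted.size
                frontier = accepted
            values[seed] = cluster_size
            visited[touched] = False

    return LocalFCMap(
        values=values.reshape(shape),
        statistic="lfcd",
        mask=incl,
        affine=v.affine,
        corr_threshold=r_threshold,
        snr_threshold=None,
    )


def _chain_components(table: np.ndarray, exceed: np.ndarray, inc_flat: np.ndarray):
    """Connected components of the neighbor-correlation-exceedance graph."""
    n_vox = table.shape[0]
    seen = np.zeros(n_vox, dtype=bool)
    components = []
    for start in np.flatnonzero(inc_flat & exceed.any(axis=1)):
        if seen[start]:
            continue
        stack = [start]
        seen[start] = True
        members = []
        while stack:
            u = stack.pop()
            members.append(u)
            nbs = table[u][exceed[u]]
            for w in nbs:
                if not seen[w]:
                    seen[w] = True
                    stack.append(w)
        components.append(np.array(members, dtype=np.intp))
    return components


def _box_sum(arr: np.ndarray, cube: int) -> np.ndarray:
    """Clipped cubic-neighborhood sum over the three spatial axes.

    Values outside the array count as zero, matching a neighborhood clipped
    at the volume edge. Works on 3D volumes and on 4D (x, y, z, t) stacks.
    """
    size = (cube, cube, cube) + (1,) * (arr.ndim - 3)
    return uniform_filter(arr, size=size, mode="constant", cval=0.0) * cube**3


def foca_map(v: VolumeSeries, scheme: NeighborhoodScheme | None = None,
             combine: str = "mean") -> LocalFCMap:
    """Spatio-temporal consistency of local activity (FOCA).

    For each included voxel's clipped cubic neighborhood N (in-mask members
    only, the voxel itself included):

    * temporal component T: mean pairwise Pearson correlation among the
      member time courses;
    * spatial component S: mean Pearson correlation between the neighborhood
      value-pattern at time t and at t+1, averaged over frame pairs (a frame
      pair with a zero-variance pattern is skipped and logged).

    The raw value is (T + S)/2 by default (``combine`` also accepts
    ``"geometric"`` and ``"product"``). Voxels with fewer than 2 in-mask
    neighbors get 0. Negative raw values are kept.

    Vectorization note: with unit-norm, zero-mean member time courses z_i,
    sum_{i<j} z_i.z_j = (||sum_i z_i||^2 - N)/2, so T reduces to cubic box
    sums; S likewise reduces to box sums of x_t, x_t^2 and x_t*x_{t+1}.
    """
    if scheme is None:
        scheme = NeighborhoodScheme()
    if combine not in ("mean", "geometric", "product"):
        raise ValueError(f"unknown FOCA combination {combine!r}")
    cube = scheme.foca_cube
    t = v.n_timepoints
    if t < 3:
        raise ValueError("FOCA undefined for fewer than 3 timepoints")

    shape = v.data.shape[:3]
    dtype = v.data.dtype
    z, incl = _normalized_timeseries(v.data, v.mask)
    z4 = z.reshape(*shape, t)
    m = incl.astype(dtype)

    n_members = _box_sum(m, cube)
    n_members_i = np.rint(n_members)
    valid = incl & (n_members_i >= 3)  # self + at least 2 neighbors

    # temporal homogeneity from the norm of the neighborhood z-sum
    zsum = _box_sum(z4, cube)
    s2 = (zsum**2).sum(axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        T = (s2 - n_members_i) / (n_members_i * (n_members_i - 1.0))
    T = np.where(valid, T, 0.0)

    # spatial-pattern stability between consecutive frames
    x = v.data * m[..., None]
    bs1 = _box_sum(x, cube)                      # sum x_t
    bs2 = _box_sum(x**2, cube)                   # sum x_t^2
    bs12 = _box_sum(x[..., :-1] * x[..., 1:], cube)  # sum x_t x_{t+1}
    n = n_members_i[..., None]
    with np.errstate(divide="ignore", invalid="ignore"):
        cov = bs12 - bs1[..., :-1] * bs1[..., 1:] / n
        var_a = bs2[..., :-1] - bs1[..., :-1] ** 2 / n
        var_b = bs2[..., 1:] - bs1[..., 1:] ** 2 / n
        # a pattern whose variance is zero up to roundoff (relative to its
        # energy) has no defined correlation for that frame pair
        eps = np.finfo(x.dtype).eps
        tol_a = 100 * eps * bs2[..., :-1]
        tol_b = 100 * eps * bs2[..., 1:]
        pair_ok = (var_a > tol_a) & (var_b > tol_b)
        corr_t = np.where(pair_ok, cov / np.sqrt(np.where(pair_ok, var_a * var_b, 1.0)), 0.0)
    n_ok = pair_ok.sum(axis=-1)
    skipped = int(((~pair_ok) & valid[..., None]).sum())
    if skipped:
        warnings.warn(
            f"FOCA spatial component: skipped {skipped} zero-variance frame pairs"
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        S = np.where(n_ok > 0, corr_t.sum(axis=-1) / np.maximum(n_ok, 1), 0.0)
    S = np.where(valid, S, 0.0)

    if combine == "mean":
        raw = (T + S) / 2.0
    elif combine == "product":
        raw = T * S
    else:  # geometric: signed, defined only where both components positive
        raw = np.where((T > 0) & (S > 0), np.sqrt(np.abs(T * S)), 0.0)
    raw = np.where(valid, raw, 0.0)

    return LocalFCMap(
        values=raw,
        statistic="foca",
        mask=valid,
        affine=v.affine,
    )


def normalize_map(m: LocalFCMap) -> LocalFCMap:
    """Divide by the mean over included voxels (whole-brain-mean scaling)."""
    if m.normalized:
        warnings.warn("map already normalized; normalizing again")
    denom = m.values[m.mask].mean() if m.mask.any() else 0.0
    if denom <= 0:
        raise ValueError(f"cannot normalize: in-mask mean is {denom}")
    values = np.where(m.mask, m.values / denom, 0.0)
    return replace(m, values=values, normalized=True)
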