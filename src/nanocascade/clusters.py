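"""Nanoparticle-enzyme cluster assembly statistics and aggregation dynamics.

Multivalent His6-tagged enzymes (dimers, tetramers) bridge nanoparticles
into clusters. Three pieces are modelled here:

* Poisson loading - with stoichiometric self-assembly the copies of one
  enzyme per NP follow a Poisson law, truncated at the NP's binding-site
  budget.
* Geometric capacity - how many copies of a given enzyme fit on one NP,
  from the enzyme's effective radius (r = 0.066 * MW^(1/3) nm, oligomer MW
  in Da) and the scaffold geometry: spheres offer the shell at contact
  radius 4*pi*(R+r)^2, platelets their two large faces; square vs hexagonal
  packing gives the (min, max) range.
* Aggregation - event-driven cluster-cluster coagulation with the Brownian
  kernel K(i,j) = (r_i + r_j)(1/r_i + 1/r_j), r ~ size^(1/3), sampled by
  rejection. A merge event requires a bridging enzyme (valence >= 2) with a
  spare terminus on one cluster and a free binding site on the other, so
  monomeric linkers never aggregate anything, and saturated surfaces (high
  protein/NP ratio) block cluster growth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from pydantic import BaseModel, Field, model_validator
from scipy import stats

from .enzymes import EnzymeDef

__all__ = [
    "NPType",
    "LinkerSpec",
    "ClusterEnsemble",
    "NP_PRESETS",
    "poisson_loading",
    "capacity_estimate",
    "simulate_aggregation",
    "cluster_stats",
]

#: minimal protein radius prefactor, nm per Da^(1/3)
_RADIUS_PREFACTOR = 0.066
_PACK_SQUARE = math.pi / 4  # 0.785
_PACK_HEX = math.pi / (2 * math.sqrt(3))  # 0.907

#: histogram bin edges used for cluster-size distributions
SIZE_BINS = ((1, 1), (2, 4), (5, 8), (9, 16), (17, 32), (33, None))


class NPType(BaseModel):
    """A nanoparticle scaffold: sphere (quantum dot) or platelet."""

    name: str
    shape: str
    dims: tuple[float, ...]  # nm: (diameter,) or (length, width, height)
    surface_area: float = Field(gt=0)  # nm^2
    sv_ratio: float = Field(gt=0)  # 1/nm
    max_sites: int = Field(ge=1)  # binding-site budget per particle

    @model_validator(mode="after")
    def _geometry(self):
        if self.shape == "sphere":
            (d,) = self.dims
            expect = math.pi * d**2
        elif self.shape == "platelet":
            length, w, h = self.dims
            expect = 2 * (length * w + length * h + w * h)
        else:
            raise ValueError("shape must be 'sphere' or 'platelet'")
        if abs(self.surface_area - expect) > 0.01 * expect:
            raise ValueError(
                f"surface_area {self.surface_area:.1f} inconsistent with shape "
                f"({expect:.1f} nm^2 expected)"
            )
        return self


def _sphere(name: str, diameter: float, max_sites: int) -> NPType:
    area = math.pi * diameter**2
    volume = math.pi * diameter**3 / 6
    return NPType(name=name, shape="sphere", dims=(diameter,), surface_area=area,
                  sv_ratio=area / volume, max_sites=max_sites)


def _platelet(name: str, length: float, w: float, h: float, max_sites: int) -> NPType:
    area = 2 * (length * w + length * h + w * h)
    volume = length * w * h
    return NPType(name=name, shape="platelet", dims=(length, w, h),
                  surface_area=area, sv_ratio=area / volume, max_sites=max_sites)


#: the quantum dots and nanoplatelet used throughout; max_sites is the
#: capacity-range midpoint for a typical cascade enzyme on each scaffold
NP_PRESETS: dict[str, NPType] = {
    "qd520": _sphere("qd520", 4.0, 8),
    "qd600": _sphere("qd600", 9.7, 20),
    "qd660": _sphere("qd660", 13.4, 32),
    "npl": _platelet("npl", 19.2, 17.3, 2.6, 25),
}


class LinkerSpec(BaseModel):
    """One enzyme species acting as a (potential) cross-linker."""

    enzyme: EnzymeDef
    concentration: float = Field(ge=0)  # nM

    @property
    def valence(self) -> int:
        """Number of NP-binding termini (one His6 per subunit)."""
        return self.enzyme.subunits


@dataclass
class ClusterEnsemble:
    """Multiset of cluster sizes (NPs per cluster) from one simulation."""

    sizes: np.ndarray
    seed: int
    n_np: int
    merge_count: int
    kernel_params: dict = field(default_factory=dict)

    def __post_init__(self):
        self.sizes = np.asarray(self.sizes, dtype=int)
        if np.any(self.sizes < 1):
            raise ValueError("cluster sizes must be >= 1")
        if int(self.sizes.sum()) != self.n_np:
            raise ValueError("cluster sizes do not conserve the NP count")


def poisson_loading(
    mean_ratio: float, max_sites: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Distribution of enzyme copies per NP at a given mean stoichiometry.

    Returns (k, pmf). With a finite ``max_sites`` the Poisson pmf is
    truncated there and renormalized.
    """
    if mean_ratio < 0:
        raise ValueError("mean ratio must be non-negative")
    if mean_ratio == 0:
        return np.array([0]), np.array([1.0])
    if max_sites is None:
        k_top = int(stats.poisson.ppf(1 - 1e-9, mean_ratio))
    else:
        k_top = int(max_sites)
    k = np.arange(k_top + 1)
    pmf = stats.poisson.pmf(k, mean_ratio)
    return k, pmf / pmf.sum()


def capacity_estimate(
    np_type: NPType, monomer_mw: float, subunits: int
) -> tuple[int, int]:
    """(min, max) copies of an enzyme that fit on one nanoparticle.

    The enzyme footprint is a disc of effective radius
    r = 0.066 * (subunits * monomer_mw_Da)^(1/3) nm. Spheres are packed on
    the shell at contact radius; platelets on their two large faces. Square
    packing gives the conservative minimum, hexagonal the maximum; both are
    clamped to at least 1.
    """
    if monomer_mw <= 0 or subunits < 1:
        raise ValueError("positive monomer mass and subunit count required")
    mw_da = monomer_mw * 1e3 * subunits
    r_enz = _RADIUS_PREFACTOR * mw_da ** (1.0 / 3.0)
    footprint = math.pi * r_enz**2
    if footprint >= np_type.surface_area:
        return 1, 1  # the particle decorates the enzyme, not vice versa

    if np_type.shape == "sphere":
        (d,) = np_type.dims
        accessible = 4 * math.pi * (d / 2 + r_enz) ** 2
    else:
        length, w, _ = np_type.dims
        accessible = 2 * length * w

    lo = max(1, math.floor(accessible * _PACK_SQUARE / footprint))
    hi = max(1, math.floor(accessible * _PACK_HEX / footprint))
    if lo > hi:
        lo, hi = hi, lo
    return lo, hi


def _kernel(size_i: float, size_j: float, shape_factor: float) -> float:
    """Brownian coagulation kernel with r ~ size^(1/3)."""
    ri, rj = size_i ** (1.0 / 3.0), size_j ** (1.0 / 3.0)
    return shape_factor * (ri + rj) * (1.0 / ri + 1.0 / rj)


def _langmuir_bound(l_tot: float, s_tot: float, kd: float) -> float:
    """Bound ligand at equilibrium for total ligand/sites (same units) and Kd."""
    if l_tot <= 0 or s_tot <= 0:
        return 0.0
    # free ligand solves L_f^2 + L_f (Kd + S - L) - Kd L = 0
    b = kd + s_tot - l_tot
    l_free = (-b + math.sqrt(b * b + 4 * kd * l_tot)) / 2
    return l_tot - l_free


def simulate_aggregation(
    np_conc: float,
    np_type: NPType,
    linkers: list[LinkerSpec],
    t_steps: int | None = None,
    seed: int = 0,
    particles_per_nM: float = 40.0,
    platelet_factor: float = 2.0,
    kd_nM: float = 1.0,
    sim_time: float = 0.15,
) -> ClusterEnsemble:
    """Stochastic cluster-cluster aggregation of NP-enzyme assemblies.

    Enzymes first adsorb to particle binding sites at Langmuir equilibrium
    (metal-affinity coordination with dissociation constant ``kd_nM``); the
    equilibrium occupancy leaves a small free-site fraction even in enzyme
    excess. Clusters then undergo collision events drawn from the Brownian
    kernel by rejection sampling; a collision becomes a merge only if one
    partner carries a bridging enzyme with a spare His6 terminus
    (valence >= 2) and the other still has a free binding site - so
    monomeric linkers never aggregate anything, and saturated surfaces
    (high protein/NP ratio) suppress cluster growth.

    Events follow a thinned Gillespie scheme: candidate collisions occur at
    the kernel-bound rate in a volume fixed by the particle concentration,
    so coagulation is faster - and final clusters larger - at higher NP
    concentration, and the run stops at a finite assembly time ``sim_time``
    (dimensionless kernel units; the default leaves aggregation partial, as
    in a finite incubation). ``t_steps`` optionally caps the number of
    attempted events instead.

    Parameters
    ----------
    np_conc : float
        Particle concentration, nM; the discrete particle count is
        ``round(np_conc * particles_per_nM)``.
    """
    rng = np.random.default_rng(seed)
    n_np = max(2, int(round(np_conc * particles_per_nM)))
    if t_steps is None:
        t_steps = 50 * n_np  # safety cap; sim_time normally terminates first
    shape_factor = platelet_factor if np_type.shape == "platelet" else 1.0
    volume = n_np / np_conc  # so the initial number density equals np_conc

    # --- adsorption at binding equilibrium
    copies = np.array(
        [link.valence - 1
         for link in linkers
         for _ in range(int(round(link.concentration * particles_per_nM)))],
        dtype=int,
    )  # spare-termini contribution of each enzyme copy
    total_sites = n_np * np_type.max_sites
    l_tot_nM = sum(link.concentration for link in linkers)
    bound_frac = 0.0
    if l_tot_nM > 0:
        bound_frac = _langmuir_bound(
            l_tot_nM, total_sites / particles_per_nM, kd_nM
        ) / l_tot_nM
    n_bound = min(int(round(bound_frac * copies.size)), total_sites, copies.size)

    free_sites = np.full(n_np, np_type.max_sites, dtype=int)
    spare_termini = np.zeros(n_np, dtype=int)
    if n_bound > 0:
        which = rng.choice(copies.size, size=n_bound, replace=False)
        # uniform over sites without replacement -> respects per-NP capacity
        site_owner = np.repeat(np.arange(n_np), np_type.max_sites)
        slots = rng.choice(total_sites, size=n_bound, replace=False)
        for copy_idx, slot in zip(which, slots):
            p = site_owner[slot]
            free_sites[p] -= 1
            spare_termini[p] += copies[copy_idx]

    # --- aggregation: union of particles into clusters
    sizes = {c: 1 for c in range(n_np)}
    cl_sites = {c: int(free_sites[c]) for c in range(n_np)}
    cl_termini = {c: int(spare_termini[c]) for c in range(n_np)}
    merges = 0

    any_bridges = any(v > 0 for v in cl_termini.values())
    if any_bridges:
        ids = list(sizes)
        cur_max = 1  # largest cluster size so far; bounds the kernel
        t_now = 0.0
        for _ in range(int(t_steps)):
            if len(ids) < 2:
                break
            k_max = _kernel(1, cur_max, shape_factor)
            n_cl = len(ids)
            rate_max = n_cl * (n_cl - 1) / 2 * k_max / volume
            t_now += rng.exponential(1.0 / rate_max)
            if t_now > sim_time:
                break
            i, j = rng.choice(n_cl, size=2, replace=False)
            ci, cj = ids[i], ids[j]
            if rng.random() >= _kernel(sizes[ci], sizes[cj], shape_factor) / k_max:
                continue
            bridgeable = (cl_termini[ci] > 0 and cl_sites[cj] > 0) or (
                cl_termini[cj] > 0 and cl_sites[ci] > 0
            )
            if not bridgeable:
                continue
            # consume one spare terminus on the donor, one site on the acceptor
            if cl_termini[ci] > 0 and cl_sites[cj] > 0:
                cl_termini[ci] -= 1
                cl_sites[cj] -= 1
            else:
                cl_termini[cj] -= 1
                cl_sites[ci] -= 1
            sizes[ci] += sizes[cj]
            cl_sites[ci] += cl_sites[cj]
            cl_termini[ci] += cl_termini[cj]
            del sizes[cj], cl_sites[cj], cl_termini[cj]
            ids = list(sizes)
            cur_max = max(cur_max, sizes[ci])
            merges += 1

    return ClusterEnsemble(
        sizes=np.array(sorted(sizes.values(), reverse=True)),
        seed=seed, n_np=n_np, merge_count=merges,
        kernel_params={
            "shape_factor": shape_factor, "t_steps": int(t_steps),
            "particles_per_nM": particles_per_nM, "np_type": np_type.name,
        },
    )


@dataclass
class ClusterStats:
    """Summary statistics of a cluster ensemble."""

    mean_size: float
    np_weighted_mean: float
    histogram: dict[str, int]
    np_weighted_histogram: dict[str, int]


def _bin_label(lo: int, hi: int | None) -> str:
    if hi is None:
        return f">{lo - 1}"
    return str(lo) if lo == hi else f"{lo}-{hi}"


def cluster_stats(ensemble: ClusterEnsemble) -> ClusterStats:
    """Mean sizes and binned histograms (cluster-count and NP-weighted).

    The NP-weighted histogram weights each cluster by the number of
    particles it contains, i.e. it answers "how many NPs sit in clusters of
    this size band" rather than "how many clusters fall in the band".
    """
    sizes = ensemble.sizes
    if sizes.size == 0:
        raise ValueError("empty ensemble")
    hist: dict[str, int] = {}
    np_hist: dict[str, int] = {}
    for lo, hi in SIZE_BINS:
        label = _bin_label(lo, hi)
        mask = sizes >= lo if hi is None else (sizes >= lo) & (sizes <= hi)
        hist[label] = int(mask.sum())
        np_hist[label] = int(sizes[mask].sum())
    return ClusterStats(
        mean_size=float(sizes.mean()),
        np_weighted_mean=float((sizes**2).sum() / sizes.sum()),
        histogram=hist,
        np_weighted_histogram=np_hist,
    )
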