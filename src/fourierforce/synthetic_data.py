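"""Synthetic labeled datasets from analytic pair potentials, plus MD validation.

Lennard-Jones and Morse cluster (or small periodic box) datasets carry exact
analytic energies and forces, so every stage of the training pipeline can be
tested without external reference data.  A minimal velocity-Verlet NVE
integrator probes force conservativeness at the integration level, and
radial-distribution-function utilities provide the structural error metric
sqrt(integral (g - g_ref)^2 dr).

Units: eV, Angstrom, fs, amu, Kelvin throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .structures_io import AtomicConfiguration, build_neighbor_list

__all__ = [
    "PairPotentialParams",
    "Trajectory",
    "RDFResult",
    "pair_reference",
    "generate_cluster_dataset",
    "nve_run",
    "compute_rdf",
    "rdf_error",
    "KB_EV",
    "ATOMIC_MASSES",
]

#: Boltzmann constant, eV/K.
KB_EV = 8.617333262e-5
#: Acceleration conversion: (eV/Angstrom)/amu -> Angstrom/fs^2.
_ACC = 9.648533212e-3
#: Kinetic-energy conversion: amu * (Angstrom/fs)^2 -> eV.
_KIN = 1.0 / _ACC

ATOMIC_MASSES: dict[str, float] = {
    "H": 1.008, "He": 4.0026, "Li": 6.94, "C": 12.011, "N": 14.007,
    "O": 15.999, "F": 18.998, "Ne": 20.180, "Na": 22.990, "Mg": 24.305,
    "Al": 26.982, "Si": 28.085, "P": 30.974, "S": 32.06, "Cl": 35.45,
    "Ar": 39.948, "K": 39.098, "Ca": 40.078, "Ti": 47.867, "Fe": 55.845,
    "Ni": 58.693, "Cu": 63.546, "Kr": 83.798, "Ag": 107.868, "Xe": 131.293,
    "Pt": 195.084, "Au": 196.967,
}


@dataclass(frozen=True)
class PairPotentialParams:
    """Analytic pair potential acting as the exact label oracle.

    family : "lennard-jones" (epsilon eV, sigma Angstrom) or
             "morse" (De eV, a 1/Angstrom, re Angstrom).
    pairs : mapping from unordered species pair to its parameter dict.
    cutoff : interaction cutoff, Angstrom; the pair energy is shifted so it
             vanishes continuously at the cutoff.
    """

    family: str
    pairs: dict
    cutoff: float

    def __post_init__(self) -> None:
        if self.family not in ("lennard-jones", "morse"):
            raise ValueError(f"unknown pair-potential family {self.family!r}")
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")
        for key, p in self.pairs.items():
            if any(v <= 0 for v in p.values()):
                raise ValueError(f"non-positive parameter for pair {key}")
            ref = p["sigma"] if self.family == "lennard-jones" else p["re"]
            if self.cutoff <= ref:
                raise ValueError("cutoff must exceed the pair length parameter")

    def lookup(self, s1: str, s2: str) -> dict:
        for key in ((s1, s2), (s2, s1)):
            if key in self.pairs:
                return self.pairs[key]
        raise KeyError(f"no parameters for species pair ({s1}, {s2})")


def _pair_energy_dvdr(params: PairPotentialParams, p: dict, r: np.ndarray):
    """v(r) (cutoff-shifted) and dv/dr for an array of distances."""
    if params.family == "lennard-jones":
        def v_raw(rr):
            sr6 = (p["sigma"] / rr) ** 6
            return 4.0 * p["epsilon"] * (sr6 ** 2 - sr6)
        sr6 = (p["sigma"] / r) ** 6
        dvdr = 4.0 * p["epsilon"] * (-12.0 * sr6 ** 2 + 6.0 * sr6) / r
    else:  # morse
        def v_raw(rr):
            e = np.exp(-p["a"] * (rr - p["re"]))
            return p["De"] * ((1.0 - e) ** 2 - 1.0)
        e = np.exp(-p["a"] * (r - p["re"]))
        dvdr = 2.0 * p["De"] * p["a"] * e * (1.0 - e)
    return v_raw(r) - v_raw(np.asarray(params.cutoff)), dvdr


def pair_reference(config: AtomicConfiguration,
                   params: PairPotentialParams) -> tuple[float, np.ndarray]:
    """Exact analytic energy (eV) and forces (eV/Angstrom) of the pair model.

    Periodic systems use the images within the cutoff (minimum image when the
    cutoff is at most half the box).
    """
    nl = build_neighbor_list(config, params.cutoff)
    energy = 0.0
    forces = np.zeros((config.n_atoms, 3))
    if nl.n_pairs == 0:
        return energy, forces
    if np.any(nl.distances <= 0.0):
        raise ValueError("coincident atoms (zero pair distance)")
    for p_idx in range(nl.n_pairs):
        i, j = nl.centers[p_idx], nl.neighbors[p_idx]
        r = nl.distances[p_idx]
        u = nl.displacements[p_idx] / r
        par = params.lookup(config.species[i], config.species[j])
        v, dvdr = _pair_energy_dvdr(params, par, np.asarray(r))
        energy += 0.5 * float(v)       # directed pairs are double counted
        forces[i] += float(dvdr) * u   # -dE/dpos_i for this bond
    return energy, forces


def generate_cluster_dataset(n_configs: int, n_atoms: int, species,
                             params: PairPotentialParams,
                             jitter: float, min_distance: float, seed: int,
                             spacing: float | None = None,
                             box: float | None = None,
                             max_retries: int = 200) -> list[AtomicConfiguration]:
    """Labeled configurations from jittered lattice sites.

    Atoms sit on a cubic lattice (spacing defaults to the potential's
    equilibrium distance) and are perturbed by isotropic Gaussian jitter;
    draws violating the minimum pair distance are rejected and resampled.
    With ``box`` set, the lattice is wrapped in a periodic cubic cell of that
    edge.  Every configuration is labeled by :func:`pair_reference` and the
    whole dataset is reproducible from the seed.
    """
    species = list(species)
    if len(species) == 1:
        species = species * n_atoms
    if len(species) != n_atoms:
        raise ValueError("species must be one symbol or a length-n_atoms list")
    if spacing is None:
        p = params.lookup(species[0], species[0])
        spacing = (2.0 ** (1.0 / 6.0) * p["sigma"]
                   if params.family == "lennard-jones" else p["re"])

    side = int(np.ceil(n_atoms ** (1.0 / 3.0)))
    grid = np.array([(x, y, z) for x in range(side) for y in range(side)
                     for z in range(side)][:n_atoms], dtype=float) * spacing
    rng = np.random.default_rng(seed)
    cell = None if box is None else np.eye(3) * box
    pbc = (False,) * 3 if box is None else (True,) * 3

    configs = []
    for _ in range(n_configs):
        for attempt in range(max_retries):
            pos = grid + rng.normal(0.0, jitter, size=grid.shape)
            trial = AtomicConfiguration(pos, species, cell=cell, pbc=pbc)
            dmin = (build_neighbor_list(trial, min_distance).distances.min()
                    if build_neighbor_list(trial, min_distance).n_pairs else np.inf)
            if dmin >= min_distance or dmin == np.inf:
                break
        else:
            raise RuntimeError(
                f"could not place {n_atoms} atoms at min distance {min_distance} "
                f"after {max_retries} tries")
        energy, forces = pair_reference(trial, params)
        configs.append(AtomicConfiguration(trial.positions, species, cell=cell,
                                           pbc=pbc, energy=energy, forces=forces))
    return configs


# ---------------------------------------------------------------------------
# NVE molecular dynamics (velocity Verlet)
# ---------------------------------------------------------------------------

@dataclass
class Trajectory:
    """Ordered MD frames with per-frame energy bookkeeping."""

    frames: list[AtomicConfiguration]
    timestep: float  # fs
    potential_energy: np.ndarray
    kinetic_energy: np.ndarray

    @property
    def total_energy(self) -> np.ndarray:
        return self.potential_energy + self.kinetic_energy


def _energy_force_fn(model):
    """Accept a TrainedPotential, PairPotentialParams, or callable."""
    if isinstance(model, PairPotentialParams):
        return lambda cfg: pair_reference(cfg, model)
    if hasattr(model, "get_energy") and hasattr(model, "get_forces"):
        from .potential import predict
        return lambda cfg: predict(cfg, model)
    if callable(model):
        return model
    raise TypeError(f"cannot evaluate energies/forces with {type(model)!r}")


def maxwell_boltzmann_velocities(masses: np.ndarray, temperature: float,
                                 rng: np.random.Generator) -> np.ndarray:
    """Thermal velocities (Angstrom/fs) with the net momentum removed."""
    sigma_v = np.sqrt(KB_EV * temperature / (_KIN * masses))
    v = rng.normal(size=(masses.size, 3)) * sigma_v[:, None]
    v -= (masses[:, None] * v).sum(axis=0) / masses.sum()
    return v


def nve_run(model, initial: AtomicConfiguration, timestep: float, steps: int,
            temperature: float = 0.0, seed: int = 0,
            masses: dict[str, float] | None = None) -> Trajectory:
    """Microcanonical velocity-Verlet integration.

    Initial velocities are Maxwell-Boltzmann at ``temperature`` with zero net
    momentum.  Total energy per frame is recorded; its drift is the
    integration-level check that the force field is conservative.
    """
    if timestep <= 0:
        raise ValueError("timestep must be positive")
    ef = _energy_force_fn(model)
    mass_table = ATOMIC_MASSES if masses is None else {**ATOMIC_MASSES, **masses}
    try:
        m = np.array([mass_table[s] for s in initial.species])
    except KeyError as exc:
        raise KeyError(f"no atomic mass for species {exc.args[0]!r}") from None

    rng = np.random.default_rng(seed)
    pos = initial.positions.copy()
    vel = (maxwell_boltzmann_velocities(m, temperature, rng)
           if temperature > 0 else np.zeros_like(pos))

    def snapshot(p):
        return AtomicConfiguration(p.copy(), initial.species, cell=initial.cell,
                                   pbc=initial.pbc)

    epot, forces = ef(snapshot(pos))
    frames = [snapshot(pos)]
    pe = [epot]
    ke = [0.5 * _KIN * float((m[:, None] * vel ** 2).sum())]
    acc = _ACC * forces / m[:, None]
    dt = timestep
    for step in range(steps):
        pos = pos + vel * dt + 0.5 * acc * dt ** 2
        epot, forces = ef(snapshot(pos))
        if not np.all(np.isfinite(forces)):
            raise FloatingPointError(f"non-finite forces at step {step + 1}")
        acc_new = _ACC * forces / m[:, None]
        vel = vel + 0.5 * (acc + acc_new) * dt
        acc = acc_new
        frames.append(snapshot(pos))
        pe.append(epot)
        ke.append(0.5 * _KIN * float((m[:, None] * vel ** 2).sum()))
    return Trajectory(frames=frames, timestep=dt,
                      potential_energy=np.asarray(pe),
                      kinetic_energy=np.asarray(ke))


# ---------------------------------------------------------------------------
# radial distribution functions
# ---------------------------------------------------------------------------

@dataclass
class RDFResult:
    """Histogram estimate of g(r) on uniform bins."""

    r: np.ndarray          # bin centers, Angstrom
    g: np.ndarray
    bin_width: float
    species_pair: tuple[str, str]
    n_frames: int


def compute_rdf(trajectory: Trajectory, species_pair: tuple[str, str],
                r_max: float, bins: int) -> RDFResult:
    """Pair correlation normalized against the ideal gas at the same density.

    Counts minimum-image pair distances into uniform bins and divides by the
    expected ideal-gas count (exact spherical-shell volumes times the partner
    number density), averaged over frames.  Needs a periodic cell to define
    the number density.
    """
    frames = trajectory.frames
    if not frames:
        raise ValueError("empty trajectory")
    first = frames[0]
    if first.cell is None or not all(first.pbc):
        raise ValueError("RDF normalization needs a fully periodic cell")
    sa, sb = species_pair
    idx_a = [i for i, s in enumerate(first.species) if s == sa]
    idx_b = [i for i, s in enumerate(first.species) if s == sb]
    same = sa == sb
    if len(idx_a) < 1 or len(idx_b) < (2 if same else 1):
        raise ValueError(f"need at least two selectable atoms for pair {species_pair}")

    edges = np.linspace(0.0, r_max, bins + 1)
    counts = np.zeros(bins)
    volume = abs(np.linalg.det(first.cell))
    inv = np.linalg.inv(first.cell)
    for cfg in frames:
        diff = cfg.positions[idx_b][None, :, :] - cfg.positions[idx_a][:, None, :]
        frac = diff @ inv
        frac -= np.round(frac)
        mic = frac @ cfg.cell
        dist = np.linalg.norm(mic, axis=-1)
        if same:
            np.fill_diagonal(dist, np.inf)
        h, _ = np.histogram(dist.ravel(), bins=edges)
        counts += h
    counts /= len(frames)

    n_pairs = len(idx_a) * (len(idx_b) - 1) if same else len(idx_a) * len(idx_b)
    shell = 4.0 * np.pi / 3.0 * (edges[1:] ** 3 - edges[:-1] ** 3)
    ideal = n_pairs * shell / volume
    with np.errstate(invalid="ignore", divide="ignore"):
        g = np.where(ideal > 0, counts / ideal, 0.0)
    return RDFResult(r=0.5 * (edges[1:] + edges[:-1]), g=g,
                     bin_width=float(edges[1] - edges[0]),
                     species_pair=(sa, sb), n_frames=len(frames))


def rdf_error(g: np.ndarray, g_ref: np.ndarray, r: np.ndarray) -> float:
    """Structural error metric: sqrt(integral (g - g_ref)^2 dr).

    The integral runs over the shared binning by trapezoidal quadrature; the
    squared-difference (L2) reading avoids sign cancellation.
    """
    g = np.asarray(g, float)
    g_ref = np.asarray(g_ref, float)
    r = np.asarray(r, float)
    if g.shape != g_ref.shape or g.shape != r.shape:
        raise ValueError("g, g_ref and r must share the same binning")
    return float(np.sqrt(np.trapezoid((g - g_ref) ** 2, r)))
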