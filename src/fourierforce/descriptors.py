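"""Invariant per-atom descriptors, their position Jacobians, and standardization.

The built-in descriptor is a two-body radial design in the Behler G2 family:
for a center atom n, the channel indexed by (species s, radial center mu_q)
accumulates a Gaussian of the center-neighbor distance times a smooth cosine
cutoff, summed over all species-s neighbors within the cutoff radius,

    H[n, (s, q)] = sum_{m : species(m) = s, r_nm <= r_c}
                   exp(-(r_nm - mu_q)^2 / (2 eta^2)) * f_cut(r_nm),

with f_cut(r) = (cos(pi r / r_c) + 1) / 2.  It is invariant under rigid
motions and relabeling of identical atoms by construction, and its position
Jacobian is analytic.  External descriptor backends (e.g. features extracted
from a frozen pre-trained graph network) plug in through the provider
registry; the same invariants are contracts on any provider.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Protocol, runtime_checkable

import numpy as np

from .structures_io import AtomicConfiguration, build_neighbor_list

__all__ = [
    "DescriptorSpec",
    "DescriptorResult",
    "Standardizer",
    "compute_descriptors",
    "compute_descriptor_jacobian",
    "fit_standardizer",
    "standardize",
    "scale_jacobian",
    "register_provider",
    "get_provider",
    "DescriptorProvider",
]

_SCALE_FLOOR = 1e-8  # below this a column counts as constant and gets scale 1


@dataclass(frozen=True)
class DescriptorSpec:
    """Hyperparameters of the built-in radial descriptor.

    cutoff : interaction radius r_c, Angstrom.
    centers : radial Gaussian centers mu_q in [0, r_c], Angstrom.
    eta : Gaussian smearing width, Angstrom.
    species : ordered vocabulary of chemical symbols (defines channel order).
    """

    cutoff: float
    centers: tuple[float, ...]
    eta: float
    species: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")
        if self.eta <= 0:
            raise ValueError("eta must be positive")
        if len(self.centers) < 1:
            raise ValueError("need at least one radial center")
        if any(c < 0 or c > self.cutoff for c in self.centers):
            raise ValueError("radial centers must lie in [0, cutoff]")
        if len(self.species) < 1:
            raise ValueError("empty species vocabulary")

    @property
    def n_centers(self) -> int:
        return len(self.centers)

    @property
    def dimension(self) -> int:
        return len(self.species) * len(self.centers)

    @staticmethod
    def default(species: tuple[str, ...] | list[str],
                cutoff: float = 5.0, n_centers: int = 8,
                eta: float | None = None) -> "DescriptorSpec":
        """Smooth overlapping default basis: centers uniform on [0, r_c],
        eta = r_c / Q."""
        centers = tuple(np.linspace(0.0, cutoff, n_centers))
        return DescriptorSpec(
            cutoff=cutoff, centers=centers,
            eta=cutoff / n_centers if eta is None else eta,
            species=tuple(species),
        )


@dataclass
class DescriptorResult:
    """Per-atom descriptors and, optionally, their position Jacobian.

    H : (N, d) dimensionless descriptor rows, one per atom.
    J : (N, d, N, 3) array with J[n, i, m, k] = dH[n, i]/dpositions[m, k],
        1/Angstrom, or None when only descriptors were requested.  Entries
        vanish outside the cutoff neighborhood of atom n.
    """

    H: np.ndarray
    J: np.ndarray | None = None


@runtime_checkable
class DescriptorProvider(Protocol):
    """Adapter contract for external descriptor backends.

    A provider is frozen: ``describe`` never updates internal parameters.
    Returned arrays must satisfy the DescriptorResult invariants (rigid-motion
    invariance of H, translation nullity of J).
    """

    dimension: int
    species: tuple[str, ...]

    def describe(self, config: AtomicConfiguration) -> tuple[np.ndarray, np.ndarray]:
        ...


_PROVIDERS: dict[str, DescriptorProvider] = {}


def register_provider(name: str, provider: DescriptorProvider) -> None:
    _PROVIDERS[name] = provider


def get_provider(name: str) -> DescriptorProvider:
    try:
        return _PROVIDERS[name]
    except KeyError:
        raise KeyError(f"no descriptor provider registered under {name!r}") from None


def _check_species(config: AtomicConfiguration, vocabulary: tuple[str, ...]) -> None:
    unknown = sorted(set(config.species) - set(vocabulary))
    if unknown:
        raise ValueError(f"species outside vocabulary: {', '.join(unknown)}")


def _radial_terms(spec: DescriptorSpec, dist: np.ndarray):
    """Gaussian*cutoff values g (P, Q) and their radial derivatives dg/dr."""
    mu = np.asarray(spec.centers)
    delta = dist[:, None] - mu[None, :]
    gauss = np.exp(-(delta ** 2) / (2.0 * spec.eta ** 2))
    fc = 0.5 * (np.cos(np.pi * dist / spec.cutoff) + 1.0)
    dfc = -0.5 * np.pi / spec.cutoff * np.sin(np.pi * dist / spec.cutoff)
    g = gauss * fc[:, None]
    dg = gauss * (-(delta / spec.eta ** 2) * fc[:, None] + dfc[:, None])
    return g, dg


def compute_descriptors(config: AtomicConfiguration, spec: DescriptorSpec) -> DescriptorResult:
    """Evaluate the built-in radial descriptor (no Jacobian)."""
    return _compute(config, spec, with_jacobian=False)


def compute_descriptor_jacobian(config: AtomicConfiguration,
                                spec: DescriptorSpec) -> DescriptorResult:
    """Evaluate descriptors together with the exact analytic position Jacobian."""
    return _compute(config, spec, with_jacobian=True)


def _compute(config: AtomicConfiguration, spec: DescriptorSpec,
             with_jacobian: bool) -> DescriptorResult:
    _check_species(config, spec.species)
    n = config.n_atoms
    q = spec.n_centers
    d = spec.dimension
    sidx = {s: i for i, s in enumerate(spec.species)}

    H = np.zeros((n, d))
    J = np.zeros((n, d, n, 3)) if with_jacobian else None

    nl = build_neighbor_list(config, spec.cutoff)
    if nl.n_pairs:
        g, dg = _radial_terms(spec, nl.distances)
        chan = np.array([sidx[config.species[m]] for m in nl.neighbors])
        for p in range(nl.n_pairs):
            i, m, c = nl.centers[p], nl.neighbors[p], chan[p]
            sl = slice(c * q, (c + 1) * q)
            H[i, sl] += g[p]
            if with_jacobian:
                u = nl.displacements[p] / nl.distances[p]
                contrib = dg[p][:, None] * u[None, :]
                J[i, sl, m, :] += contrib
                J[i, sl, i, :] -= contrib
    return DescriptorResult(H=H, J=J)


# ---------------------------------------------------------------------------
# per-species standardization
# ---------------------------------------------------------------------------

@dataclass
class Standardizer:
    """Affine per-species centering and scaling of descriptor rows.

    Means and scales are computed over all training atoms of each species
    (population standard deviation); near-constant columns get unit scale so
    the map stays invertible.
    """

    species: tuple[str, ...]
    means: dict[str, np.ndarray]
    scales: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        for s in self.species:
            if np.any(self.scales[s] <= 0):
                raise ValueError(f"non-positive scale for species {s}")


def fit_standardizer(H: np.ndarray, species_tags: list[str] | tuple[str, ...],
                     vocabulary: tuple[str, ...]) -> Standardizer:
    """Fit per-species means and population standard deviations.

    H is the stacked (n_atoms, d) descriptor matrix over the training split;
    species_tags labels each row.  Every vocabulary species must appear.
    """
    H = np.asarray(H, dtype=float)
    tags = np.asarray(species_tags)
    missing = [s for s in vocabulary if not np.any(tags == s)]
    if missing:
        raise ValueError(f"no training atoms for species: {', '.join(missing)}")
    means, scales = {}, {}
    for s in vocabulary:
        rows = H[tags == s]
        means[s] = rows.mean(axis=0)
        sd = rows.std(axis=0)  # population convention
        scales[s] = np.where(sd < _SCALE_FLOOR, 1.0, sd)
    return Standardizer(species=tuple(vocabulary), means=means, scales=scales)


def standardize(H: np.ndarray, species_tags, standardizer: Standardizer) -> np.ndarray:
    """Z[n] = (H[n] - mean_{species(n)}) / scale_{species(n)}."""
    H = np.asarray(H, dtype=float)
    Z = np.empty_like(H)
    for n, s in enumerate(species_tags):
        if s not in standardizer.means:
            raise ValueError(f"species {s!r} was not seen at standardizer fit time")
        Z[n] = (H[n] - standardizer.means[s]) / standardizer.scales[s]
    return Z


def scale_jacobian(J: np.ndarray, species_tags, standardizer: Standardizer) -> np.ndarray:
    """Propagate the standardization through a descriptor Jacobian.

    The affine map has constant slope 1/scale per channel, so the Jacobian of
    the standardized descriptors is J divided by the center atom's scales.
    """
    J = np.asarray(J, dtype=float)
    out = np.empty_like(J)
    for n, s in enumerate(species_tags):
        if s not in standardizer.scales:
            raise ValueError(f"species {s!r} was not seen at standardizer fit time")
        out[n] = J[n] / standardizer.scales[s][:, None, None]
    return out
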