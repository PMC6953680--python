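"""Core genotype container for diploid microsatellite data.

Alleles are stored as fragment sizes in base pairs (positive integers); a
single sentinel value marks missing genes. Genotypes are either fully typed or
fully missing at a locus — half calls are rejected at construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

#: Sentinel for a missing gene (STRUCTURE convention).
MISSING: int = -9


@dataclass(frozen=True)
class LocusInfo:
    """Descriptor for one microsatellite locus.

    Parameters
    ----------
    id : str
        Locus identifier.
    motif_length : int
        Repeat-motif length in base pairs (>= 1). Used to convert fragment
        sizes to repeat units.
    allelic_range : int
        Max observed size minus min observed size, in ladder steps
        (``(max - min) // motif_length``); 0 for monomorphic or untyped loci.
    """

    id: str
    motif_length: int = 2
    allelic_range: int = 0

    def __post_init__(self) -> None:
        if self.motif_length < 1:
            raise ValueError(f"locus {self.id}: motif_length must be >= 1")
        if self.allelic_range < 0:
            raise ValueError(f"locus {self.id}: allelic_range must be >= 0")


@dataclass
class GenotypeDataset:
    """Individuals x loci x 2 diploid allele-size matrix with population labels.

    Attributes
    ----------
    individuals : list of str
        Individual identifiers, one per row of ``calls``.
    populations : dict
        Individual id -> population label; every individual has exactly one.
    loci : list of LocusInfo
    calls : ndarray of int, shape (n_individuals, n_loci, 2)
        Allele sizes in bp; both slots of a genotype are either typed
        (positive) or :data:`MISSING`.
    """

    individuals: list[str]
    populations: dict[str, str]
    loci: list[LocusInfo]
    calls: np.ndarray
    missing_code: int = field(default=MISSING)

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int64)
        n_ind, n_loci = len(self.individuals), len(self.loci)
        if self.calls.shape != (n_ind, n_loci, 2):
            raise ValueError(
                f"calls shape {self.calls.shape} != ({n_ind}, {n_loci}, 2)"
            )
        if len(set(self.individuals)) != n_ind:
            raise ValueError("duplicate individual ids")
        missing_pop = [i for i in self.individuals if i not in self.populations]
        if missing_pop:
            raise ValueError(f"individuals without population label: {missing_pop[:5]}")
        a, b = self.calls[..., 0], self.calls[..., 1]
        half = (a == self.missing_code) != (b == self.missing_code)
        if half.any():
            i, l = np.argwhere(half)[0]
            raise ValueError(
                f"half-called genotype: individual {self.individuals[i]!r}, "
                f"locus {self.loci[l].id!r}"
            )
        typed = self.calls != self.missing_code
        if (self.calls[typed] <= 0).any():
            raise ValueError("allele sizes must be positive integers")

    # -- basic shape -------------------------------------------------------

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def locus_ids(self) -> list[str]:
        return [loc.id for loc in self.loci]

    def population_labels(self) -> list[str]:
        """Distinct population labels in order of first appearance."""
        seen: dict[str, None] = {}
        for ind in self.individuals:
            seen.setdefault(self.populations[ind], None)
        return list(seen)

    def population_indices(self) -> dict[str, np.ndarray]:
        """Population label -> integer row indices into ``calls``."""
        out: dict[str, list[int]] = {p: [] for p in self.population_labels()}
        for i, ind in enumerate(self.individuals):
            out[self.populations[ind]].append(i)
        return {p: np.asarray(ix, dtype=np.intp) for p, ix in out.items()}

    # -- masks and counts --------------------------------------------------

    def typed_mask(self) -> np.ndarray:
        """Boolean (n_individuals, n_loci): genotype fully typed."""
        return self.calls[..., 0] != self.missing_code

    def typed_locus_counts(self) -> np.ndarray:
        """Per-individual count of typed loci."""
        return self.typed_mask().sum(axis=1)

    # -- subsetting --------------------------------------------------------

    def take_individuals(self, idx: np.ndarray) -> "GenotypeDataset":
        inds = [self.individuals[i] for i in idx]
        return replace(
            self,
            individuals=inds,
            populations={i: self.populations[i] for i in inds},
            loci=list(self.loci),
            calls=self.calls[np.asarray(idx, dtype=np.intp)].copy(),
        )

    def take_loci(self, idx: np.ndarray) -> "GenotypeDataset":
        return replace(
            self,
            individuals=list(self.individuals),
            populations=dict(self.populations),
            loci=[self.loci[i] for i in idx],
            calls=self.calls[:, np.asarray(idx, dtype=np.intp)].copy(),
        )

    def with_recomputed_ranges(self) -> "GenotypeDataset":
        """Recompute each locus's ``allelic_range`` from the current calls."""
        loci = []
        for l, loc in enumerate(self.loci):
            sizes = self.calls[:, l, :]
            sizes = sizes[sizes != self.missing_code]
            rng = 0 if sizes.size == 0 else int(
                (sizes.max() - sizes.min()) // loc.motif_length
            )
            loci.append(replace(loc, allelic_range=rng))
        return replace(self, loci=loci, calls=self.calls.copy(),
                       individuals=list(self.individuals),
                       populations=dict(self.populations))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeDataset):
            return NotImplemented
        return (
            self.individuals == other.individuals
            and self.populations == other.populations
            and self.loci == other.loci
            and np.array_equal(self.calls, other.calls)
            and self.missing_code == other.missing_code
        )
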