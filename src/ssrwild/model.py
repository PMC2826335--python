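"""Core domain types for presence/absence SSR genotyping of genus *Arachis*.

The scoring model is the standard one for dominant band data: each marker
(primer pair) amplifies zero or more discrete fragment sizes in each
accession; every distinct ``(marker_id, size_bp)`` pair is one binary allele
character, scored 1 (band present) or 0 (band absent).  There is no
missing-data state — an unscored cell means absent.

Two matrices travel together through the pipeline:

* :class:`AlleleMatrix` — alleles x accessions, the 0/1 substrate for
  distances, specificity and trees;
* :class:`AmplificationMatrix` — markers x accessions, the any-band-present
  reduction used for transferability; it is always the allele-wise OR of the
  companion allele matrix.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .errors import ValidationError

#: The seven taxonomic sections covered by the analysis, in the conventional
#: survey-table order.  The vocabulary is deliberately closed: the two
#: remaining sections of the genus were not part of the survey design and
#: records naming them are rejected rather than silently pooled.
SECTIONS: tuple[str, ...] = (
    "Arachis",
    "Caulorrhizae",
    "Erectoides",
    "Heteranthae",
    "Procumbentes",
    "Triseminatae",
    "Extranervosae",
)

#: Divergence rank order from the marker-source section (Arachis = rank 0),
#: loosely following the observed transferability gradient across sections.
SECTION_DIVERGENCE_ORDER: tuple[str, ...] = (
    "Arachis",
    "Erectoides",
    "Procumbentes",
    "Heteranthae",
    "Caulorrhizae",
    "Extranervosae",
    "Triseminatae",
)

GENOMES: tuple[str, ...] = ("A", "B", "AB", "D", "unassigned")

#: Chromosome counts seen in the genus: aneuploid (18), diploid (20),
#: allotetraploid (40).
PLOIDIES: tuple[int, ...] = (18, 20, 40)

SOURCE_CLASSES: tuple[str, ...] = ("genomic", "genic")


@dataclass(frozen=True)
class Accession:
    """One germplasm accession with its taxonomic assignment.

    Genome classes (A/B/D) are cytogenetic designations defined only within
    section Arachis; AB marks the allotetraploid combination and implies
    2n = 4x = 40.  Accessions outside section Arachis carry
    ``genome="unassigned"``.
    """

    accession_id: str
    species: str
    section: str
    genome: str = "unassigned"
    ploidy: int = 20
    country: str = ""

    def __post_init__(self) -> None:
        if not self.accession_id or not str(self.accession_id).strip():
            raise ValidationError("accession_id must be a non-empty token")
        if self.section not in SECTIONS:
            raise ValidationError(
                f"unknown section {self.section!r} for accession "
                f"{self.accession_id!r}; allowed sections: {', '.join(SECTIONS)}"
            )
        if self.genome not in GENOMES:
            raise ValidationError(
                f"unknown genome {self.genome!r} for accession "
                f"{self.accession_id!r}; allowed genomes: {', '.join(GENOMES)}"
            )
        if self.ploidy not in PLOIDIES:
            raise ValidationError(
                f"ploidy {self.ploidy!r} for accession {self.accession_id!r} "
                f"not one of {PLOIDIES}"
            )
        if self.genome == "AB" and self.ploidy != 40:
            raise ValidationError(
                f"accession {self.accession_id!r}: genome AB implies "
                f"ploidy 40, got {self.ploidy}"
            )
        if self.section != "Arachis" and self.genome != "unassigned":
            raise ValidationError(
                f"accession {self.accession_id!r}: genome classes are defined "
                f"only within section Arachis; section {self.section!r} "
                f"requires genome='unassigned'"
            )

    @property
    def is_tetraploid(self) -> bool:
        return self.ploidy == 40


@dataclass
class Taxonomy:
    """The accession frame: species, sections, genome classes, ploidy."""

    accessions: list[Accession]
    cultivated_species: str = "A. hypogaea"

    def __post_init__(self) -> None:
        seen: dict[str, Accession] = {}
        species_section: dict[str, str] = {}
        for acc in self.accessions:
            if acc.accession_id in seen:
                raise ValidationError(
                    f"duplicate accession_id {acc.accession_id!r}"
                )
            seen[acc.accession_id] = acc
            prior = species_section.get(acc.species)
            if prior is not None and prior != acc.section:
                raise ValidationError(
                    f"species {acc.species!r} mapped to two sections: "
                    f"{prior!r} and {acc.section!r}"
                )
            species_section[acc.species] = acc.section
        self._by_id = seen
        self._species_section = species_section

    def __len__(self) -> int:
        return len(self.accessions)

    def ids(self) -> list[str]:
        return [a.accession_id for a in self.accessions]

    def __getitem__(self, accession_id: str) -> Accession:
        try:
            return self._by_id[accession_id]
        except KeyError:
            raise ValidationError(f"unknown accession_id {accession_id!r}") from None

    def __contains__(self, accession_id: str) -> bool:
        return accession_id in self._by_id

    def sections_present(self) -> list[str]:
        present = {a.section for a in self.accessions}
        return [s for s in SECTIONS if s in present]

    def species_present(self) -> list[str]:
        seen: list[str] = []
        for a in self.accessions:
            if a.species not in seen:
                seen.append(a.species)
        return seen

    def section_of_species(self, species: str) -> str:
        try:
            return self._species_section[species]
        except KeyError:
            raise ValidationError(f"unknown species {species!r}") from None

    def accessions_of_section(self, section: str) -> list[Accession]:
        return [a for a in self.accessions if a.section == section]

    def accessions_of_species(self, species: str) -> list[Accession]:
        return [a for a in self.accessions if a.species == species]

    def is_cultivated(self, accession_id: str) -> bool:
        return self[accession_id].species == self.cultivated_species

    def diploids(self) -> list[Accession]:
        """Non-tetraploid accessions (includes 2n=18 aneuploids)."""
        return [a for a in self.accessions if a.ploidy < 40]

    def tetraploids(self) -> list[Accession]:
        return [a for a in self.accessions if a.ploidy == 40]


@dataclass(frozen=True)
class Marker:
    """One SSR primer pair.

    ``source_class`` distinguishes markers derived from a genomic library of
    the cultivated species ("genomic") from markers mined out of conserved
    gene sequences of related genera ("genic"); the class drives the
    transferability denominators and the source-species exclusion rule.
    """

    marker_id: str
    source_class: str
    size_window: tuple[int, int]

    def __post_init__(self) -> None:
        if self.source_class not in SOURCE_CLASSES:
            raise ValidationError(
                f"marker {self.marker_id!r}: source_class must be one of "
                f"{SOURCE_CLASSES}, got {self.source_class!r}"
            )
        lo, hi = self.size_window
        if not (0 < lo < hi):
            raise ValidationError(
                f"marker {self.marker_id!r}: size_window must satisfy "
                f"0 < low < high, got {self.size_window}"
            )

    def contains_size(self, size_bp: int) -> bool:
        lo, hi = self.size_window
        return lo <= size_bp <= hi


@dataclass
class MarkerPanel:
    markers: list[Marker]

    def __post_init__(self) -> None:
        by_id: dict[str, Marker] = {}
        for m in self.markers:
            if m.marker_id in by_id:
                raise ValidationError(f"duplicate marker_id {m.marker_id!r}")
            by_id[m.marker_id] = m
        self._by_id = by_id

    def __len__(self) -> int:
        return len(self.markers)

    def __getitem__(self, marker_id: str) -> Marker:
        try:
            return self._by_id[marker_id]
        except KeyError:
            raise ValidationError(f"unknown marker_id {marker_id!r}") from None

    def __contains__(self, marker_id: str) -> bool:
        return marker_id in self._by_id

    def ids(self) -> list[str]:
        return [m.marker_id for m in self.markers]

    def of_class(self, source_class: str) -> list[Marker]:
        if source_class not in SOURCE_CLASSES:
            raise ValidationError(f"unknown source_class {source_class!r}")
        return [m for m in self.markers if m.source_class == source_class]


@dataclass(frozen=True, order=True)
class Allele:
    """One binary allele character: a fragment size at a marker."""

    marker_id: str
    size_bp: int

    def __post_init__(self) -> None:
        if self.size_bp <= 0:
            raise ValidationError(
                f"allele size must be a positive integer, got {self.size_bp!r} "
                f"at marker {self.marker_id!r}"
            )


class AlleleMatrix:
    """Binary alleles x accessions matrix.

    Rows are :class:`Allele` characters (unique ``(marker, size)`` pairs, each
    present in at least one accession); columns are accessions in taxonomy
    order.
    """

    def __init__(self, alleles: Sequence[Allele], accessions: Sequence[str],
                 cells: np.ndarray) -> None:
        self.alleles = list(alleles)
        self.accessions = list(accessions)
        self.cells = np.asarray(cells, dtype=bool)
        self.validate()
        self._allele_index = {al: i for i, al in enumerate(self.alleles)}
        self._acc_index = {a: j for j, a in enumerate(self.accessions)}

    # -- validation -------------------------------------------------------
    def validate(self) -> None:
        if self.cells.ndim != 2 or self.cells.shape != (
            len(self.alleles), len(self.accessions)
        ):
            raise ValidationError(
                f"cell matrix shape {self.cells.shape} does not match "
                f"{len(self.alleles)} alleles x {len(self.accessions)} accessions"
            )
        if len(set(self.alleles)) != len(self.alleles):
            raise ValidationError("duplicate (marker_id, size_bp) allele rows")
        if len(set(self.accessions)) != len(self.accessions):
            raise ValidationError("duplicate accession columns")
        if len(self.alleles) and not self.cells.any(axis=1).all():
            idx = int(np.flatnonzero(~self.cells.any(axis=1))[0])
            raise ValidationError(
                f"allele {self.alleles[idx]} is present in no accession"
            )

    # -- indexing helpers -------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.cells.shape

    def accession_index(self, accession_id: str) -> int:
        try:
            return self._acc_index[accession_id]
        except KeyError:
            raise ValidationError(f"unknown accession_id {accession_id!r}") from None

    def profile(self, accession_id: str) -> np.ndarray:
        """The 0/1 allele profile of one accession."""
        return self.cells[:, self.accession_index(accession_id)]

    def marker_row_indices(self) -> dict[str, list[int]]:
        rows: dict[str, list[int]] = {}
        for i, al in enumerate(self.alleles):
            rows.setdefault(al.marker_id, []).append(i)
        return rows

    def alleles_of(self, accession_id: str, marker_id: str) -> set[Allele]:
        j = self.accession_index(accession_id)
        return {
            al for i, al in enumerate(self.alleles)
            if al.marker_id == marker_id and self.cells[i, j]
        }

    def carriers(self, allele: Allele) -> list[str]:
        try:
            i = self._allele_index[allele]
        except KeyError:
            raise ValidationError(f"allele {allele} not in matrix") from None
        return [self.accessions[j] for j in np.flatnonzero(self.cells[i])]

    def subset_accessions(self, keep: Iterable[str],
                          drop_empty_alleles: bool = True) -> "AlleleMatrix":
        keep = list(keep)
        cols = [self.accession_index(a) for a in keep]
        cells = self.cells[:, cols]
        alleles = self.alleles
        if drop_empty_alleles:
            mask = cells.any(axis=1)
            cells = cells[mask]
            alleles = [al for al, m in zip(self.alleles, mask) if m]
        return AlleleMatrix(alleles, keep, cells)

    def to_amplification(self, panel: MarkerPanel | None = None) -> "AmplificationMatrix":
        """Reduce to the markers x accessions any-band-present matrix."""
        if panel is not None:
            marker_ids = panel.ids()
        else:
            marker_ids = sorted({al.marker_id for al in self.alleles})
        rows = self.marker_row_indices()
        cells = np.zeros((len(marker_ids), len(self.accessions)), dtype=bool)
        for k, mid in enumerate(marker_ids):
            idx = rows.get(mid)
            if idx:
                cells[k] = self.cells[idx].any(axis=0)
        return AmplificationMatrix(marker_ids, list(self.accessions), cells)


class AmplificationMatrix:
    """Markers x accessions boolean matrix: any sharp band present."""

    def __init__(self, markers: Sequence[str], accessions: Sequence[str],
                 cells: np.ndarray) -> None:
        self.markers = list(markers)
        self.accessions = list(accessions)
        self.cells = np.asarray(cells, dtype=bool)
        if self.cells.shape != (len(self.markers), len(self.accessions)):
            raise ValidationError(
                f"cell matrix shape {self.cells.shape} does not match "
                f"{len(self.markers)} markers x {len(self.accessions)} accessions"
            )
        if len(set(self.markers)) != len(self.markers):
            raise ValidationError("duplicate marker rows")
        self._marker_index = {m: i for i, m in enumerate(self.markers)}
        self._acc_index = {a: j for j, a in enumerate(self.accessions)}

    @property
    def shape(self) -> tuple[int, int]:
        return self.cells.shape

    def marker_index(self, marker_id: str) -> int:
        try:
            return self._marker_index[marker_id]
        except KeyError:
            raise ValidationError(f"unknown marker_id {marker_id!r}") from None

    def accession_index(self, accession_id: str) -> int:
        try:
            return self._acc_index[accession_id]
        except KeyError:
            raise ValidationError(f"unknown accession_id {accession_id!r}") from None

    def amplified(self, marker_id: str, accession_id: str) -> bool:
        return bool(
            self.cells[self.marker_index(marker_id),
                       self.accession_index(accession_id)]
        )


def check_amplification_consistency(amp: AmplificationMatrix,
                                    mat: AlleleMatrix) -> None:
    """Assert that ``amp`` is the allele-wise OR of ``mat``.

    Run after every load or simulation; a mismatch means the two matrices
    were not derived from the same band calls.
    """
    derived = mat.to_amplification()
    rows = {m: i for i, m in enumerate(derived.markers)}
    if list(amp.accessions) != list(mat.accessions):
        raise ValidationError(
            "amplification and allele matrices index different accessions"
        )
    for i, mid in enumerate(amp.markers):
        got = amp.cells[i]
        want = (
            derived.cells[rows[mid]]
            if mid in rows
            else np.zeros(len(amp.accessions), dtype=bool)
        )
        if not np.array_equal(got, want):
            j = int(np.flatnonzero(got != want)[0])
            raise ValidationError(
                f"amplification cell ({mid}, {amp.accessions[j]}) disagrees "
                f"with the allele matrix"
            )


class DistanceMatrix:
    """Symmetric matrix of Nei-Li distances in [0, 1] with a zero diagonal."""

    def __init__(self, labels: Sequence[str], values: np.ndarray) -> None:
        self.labels = list(labels)
        self.values = np.asarray(values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValidationError(
                f"distance matrix shape {self.values.shape} does not match "
                f"{n} labels"
            )
        if len(set(self.labels)) != n:
            raise ValidationError("duplicate labels in distance matrix")
        if not np.isfinite(self.values).all():
            raise ValidationError("non-finite distance entries")
        if not np.array_equal(self.values, self.values.T):
            raise ValidationError("distance matrix is not exactly symmetric")
        if np.any(np.diagonal(self.values) != 0.0):
            raise ValidationError("distance matrix diagonal is not exactly zero")
        if self.values.min() < 0.0 or self.values.max() > 1.0:
            raise ValidationError("distance entries must lie in [0, 1]")
        self._index = {lab: i for i, lab in enumerate(self.labels)}

    def __len__(self) -> int:
        return len(self.labels)

    def get(self, a: str, b: str) -> float:
        return float(self.values[self._index[a], self._index[b]])
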