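"""Taxon-specific alleles and markers, polyploid-origin and duplicated loci.

An allele is *specific* to a taxon (species or section) when every accession
carrying it belongs to that taxon in the analyzed matrix.  Specificity is
defined over the accessions actually present — a single-accession species
can legitimately own private alleles.  Because an allotetraploid carries
both diploid donors' alleles, tetraploid accessions can be excluded from
species-level scans when ground-truth comparisons require it.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from ._util import round_half_up
from .errors import ValidationError
from .model import (
    Allele,
    AlleleMatrix,
    AmplificationMatrix,
    Taxonomy,
)

LEVELS = ("species", "section")


@dataclass
class SpecificAlleleReport:
    """Taxon-specific alleles at one level, with per-taxon summary counts.

    ``rows`` columns: marker_id, size_bp, level, taxon, carriers
    (semicolon-joined accession ids).  ``summary`` columns: taxon,
    n_specific, pct — share of the grand total, rounded half-up, sorted by
    descending count.
    """

    level: str
    rows: pd.DataFrame
    summary: pd.DataFrame

    @property
    def total(self) -> int:
        return len(self.rows)

    def alleles_of(self, taxon: str) -> set[Allele]:
        sub = self.rows[self.rows.taxon == taxon]
        return {Allele(r.marker_id, int(r.size_bp)) for _, r in sub.iterrows()}

    def as_mapping(self) -> dict[str, set[Allele]]:
        return {t: self.alleles_of(t) for t in self.summary.taxon}


def specific_alleles(
    mat: AlleleMatrix,
    taxonomy: Taxonomy,
    level: str,
    exclude_accessions: tuple[str, ...] = (),
) -> SpecificAlleleReport:
    """Detect alleles whose carriers all belong to one taxon at ``level``."""
    if level not in LEVELS:
        raise ValidationError(f"level must be one of {LEVELS}, got {level!r}")
    excluded = set(exclude_accessions)
    view = mat
    if excluded:
        keep = [a for a in mat.accessions if a not in excluded]
        view = mat.subset_accessions(keep, drop_empty_alleles=True)
    rows = []
    for i, allele in enumerate(view.alleles):
        carriers = [view.accessions[j] for j in view.cells[i].nonzero()[0]]
        taxa = {getattr(taxonomy[a], level) for a in carriers}
        if len(taxa) == 1:
            rows.append(
                {
                    "marker_id": allele.marker_id,
                    "size_bp": allele.size_bp,
                    "level": level,
                    "taxon": taxa.pop(),
                    "carriers": ";".join(carriers),
                }
            )
    frame = pd.DataFrame(
        rows, columns=["marker_id", "size_bp", "level", "taxon", "carriers"]
    ).sort_values(["marker_id", "size_bp"], kind="stable").reset_index(drop=True)
    counts = frame.groupby("taxon").size() if len(frame) else pd.Series(dtype=int)
    total = int(counts.sum())
    summary = pd.DataFrame(
        {
            "taxon": counts.index,
            "n_specific": counts.to_numpy(dtype=int),
            "pct": [round_half_up(100.0 * c / total) for c in counts]
            if total
            else [],
        }
    ).sort_values(
        ["n_specific", "taxon"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)
    return SpecificAlleleReport(level, frame, summary)


def section_specific_markers(
    amp: AmplificationMatrix, taxonomy: Taxonomy
) -> list[str]:
    """Markers whose amplification is confined to exactly one section."""
    sections = taxonomy.sections_present()
    if len(sections) < 2:
        raise ValidationError("need >= 2 sections")
    out = []
    for i, marker_id in enumerate(amp.markers):
        carriers = [amp.accessions[j] for j in amp.cells[i].nonzero()[0]]
        secs = {taxonomy[a].section for a in carriers}
        if len(secs) == 1:
            out.append(marker_id)
    return sorted(out)


def polyploid_origin_markers(
    amp: AmplificationMatrix, taxonomy: Taxonomy
) -> list[str]:
    """Markers amplifying only in tetraploids — loci born of polyploidy.

    A locus amplifying in tetraploid accessions while absent from every
    diploid and aneuploid accession has no diploid progenitor copy and was
    plausibly created by the genomic restructuring that follows
    polyploidization.
    """
    tets = {a.accession_id for a in taxonomy.tetraploids()}
    if not tets:
        raise ValidationError("taxonomy contains no tetraploid accessions")
    tet_cols = [j for j, a in enumerate(amp.accessions) if a in tets]
    dip_cols = [j for j, a in enumerate(amp.accessions) if a not in tets]
    out = []
    for i, marker_id in enumerate(amp.markers):
        if amp.cells[i, tet_cols].any() and not (
            dip_cols and amp.cells[i, dip_cols].any()
        ):
            out.append(marker_id)
    return sorted(out)


def duplicated_locus_markers(
    mat: AlleleMatrix,
    taxonomy: Taxonomy,
    donor_A: str,
    donor_B: str,
) -> list[tuple[str, set[Allele]]]:
    """Markers showing the duplicated-locus signature in tetraploids.

    A marker qualifies when some tetraploid accession simultaneously carries
    at least one allele from each designated diploid donor *and* at least
    one allele absent from every diploid accession (the tetraploid-only
    extra fragment).  Returns ``(marker_id, extra_alleles)`` pairs sorted by
    marker id, where ``extra_alleles`` are all tetraploid-only alleles of
    the marker.
    """
    for donor in (donor_A, donor_B):
        if donor not in set(mat.accessions):
            raise ValidationError(f"donor accession {donor!r} not in matrix")
        if taxonomy[donor].ploidy >= 40:
            raise ValidationError(f"donor accession {donor!r} is not diploid")
    tets = [a.accession_id for a in taxonomy.tetraploids()
            if a.accession_id in set(mat.accessions)]
    dip_cols = [j for j, a in enumerate(mat.accessions)
                if taxonomy[a].ploidy < 40]
    rows = mat.marker_row_indices()
    out: list[tuple[str, set[Allele]]] = []
    for marker_id in sorted(rows):
        idx = rows[marker_id]
        a_set = mat.alleles_of(donor_A, marker_id)
        b_set = mat.alleles_of(donor_B, marker_id)
        if not a_set or not b_set:
            continue
        extra = {
            mat.alleles[i] for i in idx
            if not mat.cells[i, dip_cols].any()
        }
        if not extra:
            continue
        for t in tets:
            t_alleles = mat.alleles_of(t, marker_id)
            if (t_alleles & a_set) and (t_alleles & b_set) and (t_alleles & extra):
                out.append((marker_id, extra))
                break
    return out


def classify_donor_amplification(
    amp: AmplificationMatrix,
    mat: AlleleMatrix,
    candidate_A: str,
    candidate_B: str,
    tetraploids: list[str],
) -> dict[str, str]:
    """Classify markers by donor amplification and allele retention.

    * ``both_donors`` — amplifies both candidates and at least one allele of
      each appears in some tetraploid;
    * ``A_only`` / ``B_only`` — amplifies only that candidate, whose allele
      appears in some tetraploid;
    * ``neither`` — anything else.
    """
    if not tetraploids:
        raise ValidationError("tetraploids list must be non-empty")
    for acc in (candidate_A, candidate_B, *tetraploids):
        amp.accession_index(acc)  # raises on unknown id
    out: dict[str, str] = {}
    for marker_id in amp.markers:
        amp_a = amp.amplified(marker_id, candidate_A)
        amp_b = amp.amplified(marker_id, candidate_B)
        a_set = mat.alleles_of(candidate_A, marker_id) if amp_a else set()
        b_set = mat.alleles_of(candidate_B, marker_id) if amp_b else set()
        tet_union: set[Allele] = set()
        for t in tetraploids:
            tet_union |= mat.alleles_of(t, marker_id)
        a_in_tet = bool(a_set & tet_union)
        b_in_tet = bool(b_set & tet_union)
        if amp_a and amp_b and a_in_tet and b_in_tet:
            out[marker_id] = "both_donors"
        elif amp_a and not amp_b and a_in_tet:
            out[marker_id] = "A_only"
        elif amp_b and not amp_a and b_in_tet:
            out[marker_id] = "B_only"
        else:
            out[marker_id] = "neither"
    return out
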