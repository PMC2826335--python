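"""Cross-species / cross-section marker transferability statistics.

The central bookkeeping rule is the source-species exclusion: markers of the
"genomic" class were developed from a genomic library of the cultivated
species, so its accessions amplify them trivially and are excluded from all
transferability denominators for that class.  "Genic" markers come from
other genera, and cultivated accessions count like any other.

Two rates coexist and must not be conflated:

* *section-level* — a marker is transferable to a section when it amplifies
  in at least one scorable accession of the section (the reading that puts
  the source section at 100%);
* *accession-level* — the per-marker fraction of scorable accessions that
  amplify, averaged over markers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from ._util import round_half_up
from .errors import ValidationError
from .model import (
    AmplificationMatrix,
    MarkerPanel,
    SECTIONS,
    SOURCE_CLASSES,
    Taxonomy,
)


@dataclass
class TransferabilityTable:
    """Per-(section, class) transferable-marker counts plus class mean rows.

    ``rows`` columns: section, source_class, n_transferable, n_total, pct
    (integer percent, rounded half-up).  ``means`` holds one row per class
    with the arithmetic mean transferable count (kept exact as a float) and
    the half-up-rounded mean of the per-section percentages — the two
    figures such survey tables print in their "Mean" row.
    """

    rows: pd.DataFrame
    means: pd.DataFrame

    def __post_init__(self) -> None:
        for _, r in self.rows.iterrows():
            if not (0 <= r.n_transferable <= r.n_total):
                raise ValidationError(
                    f"row ({r.section}, {r.source_class}): counts out of range"
                )
            want = round_half_up(100.0 * r.n_transferable / r.n_total)
            if int(r.pct) != want:
                raise ValidationError(
                    f"row ({r.section}, {r.source_class}): pct {r.pct} does "
                    f"not match counts ({want})"
                )

    @classmethod
    def from_counts(
        cls, counts: dict[tuple[str, str], tuple[int, int]]
    ) -> "TransferabilityTable":
        """Build from ``{(section, source_class): (n_transferable, n_total)}``."""
        rows = []
        for section in SECTIONS:
            for source_class in SOURCE_CLASSES:
                if (section, source_class) not in counts:
                    continue
                n, total = counts[(section, source_class)]
                if total <= 0:
                    raise ValidationError(
                        f"zero marker total for class {source_class!r}"
                    )
                rows.append(
                    {
                        "section": section,
                        "source_class": source_class,
                        "n_transferable": int(n),
                        "n_total": int(total),
                        "pct": round_half_up(100.0 * n / total),
                    }
                )
        frame = pd.DataFrame(
            rows, columns=["section", "source_class", "n_transferable",
                           "n_total", "pct"]
        )
        means = []
        for source_class in SOURCE_CLASSES:
            sub = frame[frame.source_class == source_class]
            if sub.empty:
                continue
            means.append(
                {
                    "source_class": source_class,
                    "mean_count": float(sub.n_transferable.mean()),
                    "n_total": int(sub.n_total.iloc[0]),
                    "pct": round_half_up(float(sub.pct.mean())),
                }
            )
        return cls(frame, pd.DataFrame(
            means, columns=["source_class", "mean_count", "n_total", "pct"]
        ))

    def class_mean(self, source_class: str) -> tuple[float, int, int]:
        """(mean transferable count, panel size, mean percentage) for a class."""
        sub = self.means[self.means.source_class == source_class]
        if sub.empty:
            raise ValidationError(f"no mean row for class {source_class!r}")
        r = sub.iloc[0]
        return float(r.mean_count), int(r.n_total), int(r.pct)


def _scorable_ids(taxonomy: Taxonomy, source_class: str,
                  sections: set[str] | None = None) -> list[str]:
    out = []
    for acc in taxonomy.accessions:
        if sections is not None and acc.section not in sections:
            continue
        if source_class == "genomic" and acc.species == taxonomy.cultivated_species:
            continue
        out.append(acc.accession_id)
    return out


def section_transferability(
    amp: AmplificationMatrix, taxonomy: Taxonomy, panel: MarkerPanel
) -> TransferabilityTable:
    """Per-section transferable-marker counts for each marker class."""
    counts: dict[tuple[str, str], tuple[int, int]] = {}
    sections = taxonomy.sections_present()
    for source_class in SOURCE_CLASSES:
        markers = panel.of_class(source_class)
        if not markers:
            continue
        for section in sections:
            scorable = _scorable_ids(taxonomy, source_class, {section})
            scorable = [a for a in scorable if a in set(amp.accessions)]
            if not scorable:
                raise ValidationError(
                    f"section {section!r} has no scorable accessions for "
                    f"class {source_class!r}"
                )
            cols = [amp.accession_index(a) for a in scorable]
            n = sum(
                bool(amp.cells[amp.marker_index(m.marker_id), cols].any())
                for m in markers
            )
            counts[(section, source_class)] = (n, len(markers))
    return TransferabilityTable.from_counts(counts)


def accession_level_rate(
    amp: AmplificationMatrix,
    taxonomy: Taxonomy,
    panel: MarkerPanel,
    sections: set[str],
) -> float:
    """Mean over markers of the % of scorable accessions amplifying."""
    if not sections:
        raise ValidationError("sections must be non-empty")
    unknown = set(sections) - set(SECTIONS)
    if unknown:
        raise ValidationError(f"unknown sections: {sorted(unknown)}")
    fracs = []
    present = set(amp.accessions)
    for marker in panel.markers:
        scorable = [
            a for a in _scorable_ids(taxonomy, marker.source_class, set(sections))
            if a in present
        ]
        if not scorable:
            raise ValidationError(
                f"no scorable accessions for marker {marker.marker_id!r} in "
                f"sections {sorted(sections)}"
            )
        cols = [amp.accession_index(a) for a in scorable]
        row = amp.cells[amp.marker_index(marker.marker_id), cols]
        fracs.append(row.mean())
    return float(np.mean(fracs) * 100.0)


def fully_transferable_markers(
    amp: AmplificationMatrix, taxonomy: Taxonomy, panel: MarkerPanel
) -> list[str]:
    """Markers amplifying in 100% of scorable accessions, sorted by id."""
    present = set(amp.accessions)
    out = []
    for marker in panel.markers:
        scorable = [
            a for a in _scorable_ids(taxonomy, marker.source_class)
            if a in present
        ]
        if not scorable:
            continue
        cols = [amp.accession_index(a) for a in scorable]
        if amp.cells[amp.marker_index(marker.marker_id), cols].all():
            out.append(marker.marker_id)
    return sorted(out)


def single_section_null_markers(
    amp: AmplificationMatrix, taxonomy: Taxonomy
) -> dict[str, str]:
    """Markers amplifying in every section except exactly one.

    Such a pattern points at a section-wide loss of the locus or of a primer
    binding site.  The returned map sends each qualifying marker to its null
    section.
    """
    sections = taxonomy.sections_present()
    if len(sections) < 2:
        raise ValidationError("need >= 2 sections")
    cols = {
        s: [amp.accession_index(a.accession_id)
            for a in taxonomy.accessions_of_section(s)
            if a.accession_id in set(amp.accessions)]
        for s in sections
    }
    out: dict[str, str] = {}
    for i, marker_id in enumerate(amp.markers):
        null_secs = [s for s in sections if not amp.cells[i, cols[s]].any()]
        if len(null_secs) == 1:
            out[marker_id] = null_secs[0]
    return out


def two_proportion_z(x1: float, n1: int, x2: float, n2: int) -> tuple[float, float]:
    """Pooled two-proportion z-statistic and two-sided normal p-value.

    Accepts fractional successes so class *mean* transferable counts can be
    compared directly against their panel sizes.
    """
    if n1 <= 0 or n2 <= 0:
        raise ValidationError("denominators must be positive")
    if not (0 <= x1 <= n1 and 0 <= x2 <= n2):
        raise ValidationError("success counts out of range")
    p1, p2 = x1 / n1, x2 / n2
    pooled = (x1 + x2) / (n1 + n2)
    se = np.sqrt(pooled * (1.0 - pooled) * (1.0 / n1 + 1.0 / n2))
    if se == 0.0:
        return 0.0, 1.0
    z = (p1 - p2) / se
    return float(z), float(2.0 * norm.sf(abs(z)))


def compare_marker_classes(table: TransferabilityTable) -> tuple[float, float]:
    """z-test of genic vs genomic mean transferability.

    Positive z means the genic class transfers better.  The statistic is the
    pooled two-proportion z on the per-class mean transferable counts over
    the class panel sizes.
    """
    x_genic, n_genic, _ = table.class_mean("genic")
    x_genomic, n_genomic, _ = table.class_mean("genomic")
    return two_proportion_z(x_genic, n_genic, x_genomic, n_genomic)
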