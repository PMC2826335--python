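"""Published reference counts from the genus-wide *Arachis* SSR survey.

These are the printed summary numbers of the survey this package's
synthetic defaults emulate: per-section transferable-marker counts for the
82 genomic ("Ah") and 19 genic ("CS") markers, and the allele counts of the
32-marker subset used for clustering.  They parameterize the simulator's
defaults and let the printed class means and totals be recomputed with the
package's own table machinery.
"""

from __future__ import annotations

from .transferability import TransferabilityTable

#: (genomic transferable, genic transferable) markers per section, out of
#: panel sizes 82 and 19.
SECTION_TRANSFER_COUNTS: dict[str, tuple[int, int]] = {
    "Arachis": (82, 19),
    "Caulorrhizae": (56, 17),
    "Erectoides": (71, 18),
    "Heteranthae": (69, 19),
    "Procumbentes": (69, 19),
    "Triseminatae": (49, 12),
    "Extranervosae": (41, 13),
}

PANEL_SIZES: dict[str, int] = {"genomic": 82, "genic": 19}

#: Number of alleles scored per marker in the 32-marker clustering subset.
CLUSTER_PANEL_ALLELE_COUNTS: dict[str, int] = {
    "04_Dal_PHYA": 9,
    "09_Lup_CycB": 29,
    "12_Lup_ACS2": 28,
    "34_Lup_app": 23,
    "63_Stylo_IGS": 8,
    "66_Stylo_SSR4-5": 7,
    "69_Stylo_IGS": 4,
    "68_Stylo_SSR1-24": 10,
    "76_Stylo_IGS": 7,
    "IPAHM117": 11,
    "IPAHM130": 8,
    "IPAHM164": 15,
    "IPAHM165": 16,
    "IPAHM273": 10,
    "IPAHM320": 17,
    "IPAHM372": 18,
    "IPAHM357": 15,
    "IPAHM377": 13,
    "IPAHM407a": 17,
    "IPAHM409": 11,
    "IPAHM171c": 16,
    "IPAHM109": 8,
    "IPAHM324": 8,
    "IPAHM105": 18,
    "IPAHM414": 15,
    "IPAHM288": 20,
    "IPAHM82": 20,
    "IPAHM606": 16,
    "IPAHM176": 16,
    "IPAHM395": 13,
    "IAPHM245": 8,
    "IAPHM406": 20,
}


def reference_transferability_table() -> TransferabilityTable:
    """The published per-section counts as a validated table with mean rows."""
    counts = {}
    for section, (n_genomic, n_genic) in SECTION_TRANSFER_COUNTS.items():
        counts[(section, "genomic")] = (n_genomic, PANEL_SIZES["genomic"])
        counts[(section, "genic")] = (n_genic, PANEL_SIZES["genic"])
    return TransferabilityTable.from_counts(counts)


def cluster_panel_allele_total() -> int:
    """Total alleles scored across the 32-marker clustering subset."""
    return sum(CLUSTER_PANEL_ALLELE_COUNTS.values())
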