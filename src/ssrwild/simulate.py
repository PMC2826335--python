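"""Synthetic SSR genotype datasets with planted, recoverable ground truth.

The generator emulates the statistical structure of a genus-wide SSR
transferability survey:

* seven taxonomic sections with a fixed divergence rank from the
  marker-source section, and class-dependent amplification (genic markers
  transfer better than genomic ones);
* hierarchical allele pools — a global pool per marker, partially split
  into section-exclusive subsets, subsampled into per-species pools — so
  conspecific accessions cluster tightly, sections cohere, and sections
  differ, the pattern the real survey's dendrogram shows;
* species-private alleles planted at a configurable rate and recorded in a
  :class:`GroundTruth` ledger;
* one allotetraploid (AB-genome, cultivated) species whose accessions carry
  the union of two designated diploid donors' alleles, thinned by a
  retention probability; and
* tetraploid-only duplicated-locus fragments at a subset of genomic markers.

Amplification is a Bernoulli event, not a mechanistic primer-binding model;
see the methods note for what that does and does not emulate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np

from ._util import substream
from .errors import ValidationError
from .model import (
    Accession,
    Allele,
    AlleleMatrix,
    AmplificationMatrix,
    Marker,
    MarkerPanel,
    SECTION_DIVERGENCE_ORDER,
    Taxonomy,
)

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "generate_taxonomy",
    "generate_marker_panel",
    "simulate_dataset",
]


@dataclass
class SimulationConfig:
    """Knobs of the synthetic survey; defaults mirror the real study design.

    The panel is 82 genomic + 19 genic markers; base per-accession
    amplification probabilities are the published per-class mean
    transferability rates (0.76 genomic, 0.88 genic); the global allele pool
    per marker spans 4-29 alleles, the range reported for the 32-marker
    clustering subset; the cultivated tetraploid species contributes 11
    accessions as in the surveyed germplasm.
    """

    n_sections: int = 7
    species_per_section: tuple[int, int] = (4, 6)
    accessions_per_species: tuple[int, int] = (2, 3)
    cultivated_accessions: int = 11
    n_genomic_markers: int = 82
    n_genic_markers: int = 19
    base_transfer_prob: dict[str, float] = field(
        default_factory=lambda: {"genomic": 0.76, "genic": 0.88}
    )
    section_divergence_penalty: float = 0.05
    divergence_order: tuple[str, ...] = SECTION_DIVERGENCE_ORDER
    p_private_allele: float = 0.05
    p_tetraploid_locus: float = 0.1
    donor_retention: float = 0.95
    alleles_per_marker: tuple[int, int] = (4, 29)
    section_exclusive_frac: float = 0.7
    species_pool_frac: float = 0.7
    allele_presence_prob: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if not 1 <= self.n_sections <= len(self.divergence_order):
            raise ValidationError(
                f"n_sections must be in [1, {len(self.divergence_order)}]"
            )
        for name in ("species_per_section", "accessions_per_species",
                     "alleles_per_marker"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ValidationError(f"{name} range ({lo}, {hi}) is empty")
        for cls in ("genomic", "genic"):
            p = self.base_transfer_prob.get(cls)
            if p is None or not (0.0 < p <= 1.0):
                raise ValidationError(
                    f"base_transfer_prob[{cls!r}] must be in (0, 1], got {p!r}"
                )
        for name in ("p_private_allele", "p_tetraploid_locus",
                     "donor_retention", "section_exclusive_frac",
                     "species_pool_frac", "allele_presence_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1], got {v}")
        if self.section_divergence_penalty < 0:
            raise ValidationError("section_divergence_penalty must be >= 0")
        if self.n_genomic_markers < 0 or self.n_genic_markers < 0:
            raise ValidationError("marker counts must be >= 0")
        if self.cultivated_accessions < 2:
            raise ValidationError("cultivated_accessions must be >= 2")

    def sections(self) -> list[str]:
        return list(self.divergence_order[: self.n_sections])

    def divergence_rank(self, section: str) -> int:
        try:
            return self.divergence_order.index(section)
        except ValueError:
            raise ValidationError(f"section {section!r} has no divergence rank")


@dataclass
class GroundTruth:
    """What the generator planted, for recovery tests downstream."""

    donor_A: str
    donor_B: str
    private_alleles: dict[str, set[Allele]]
    section_specific_alleles: dict[str, set[Allele]]
    tetraploid_only_alleles: set[Allele]
    duplicated_locus_markers: set[str]

    def all_private(self) -> set[Allele]:
        out: set[Allele] = set()
        for s in self.private_alleles.values():
            out |= s
        return out

    def to_dict(self) -> dict:
        return {
            "donor_A": self.donor_A,
            "donor_B": self.donor_B,
            "private_alleles": {
                sp: sorted([al.marker_id, al.size_bp] for al in als)
                for sp, als in sorted(self.private_alleles.items())
            },
            "section_specific_alleles": {
                sec: sorted([al.marker_id, al.size_bp] for al in als)
                for sec, als in sorted(self.section_specific_alleles.items())
            },
            "tetraploid_only_alleles": sorted(
                [al.marker_id, al.size_bp] for al in self.tetraploid_only_alleles
            ),
            "duplicated_locus_markers": sorted(self.duplicated_locus_markers),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        return cls(
            donor_A=d["donor_A"],
            donor_B=d["donor_B"],
            private_alleles={
                sp: {Allele(m, int(s)) for m, s in als}
                for sp, als in d["private_alleles"].items()
            },
            section_specific_alleles={
                sec: {Allele(m, int(s)) for m, s in als}
                for sec, als in d["section_specific_alleles"].items()
            },
            tetraploid_only_alleles={
                Allele(m, int(s)) for m, s in d["tetraploid_only_alleles"]
            },
            duplicated_locus_markers=set(d["duplicated_locus_markers"]),
        )


# ---------------------------------------------------------------------------
# taxonomy and panel
# ---------------------------------------------------------------------------

_SECTION_ABBREV = {
    "Arachis": "ara",
    "Erectoides": "erec",
    "Procumbentes": "proc",
    "Heteranthae": "hete",
    "Caulorrhizae": "caul",
    "Extranervosae": "extr",
    "Triseminatae": "tris",
}


def generate_taxonomy(config: SimulationConfig,
                      cultivated_species: str = "A. hypogaea") -> Taxonomy:
    """Random taxonomy with the mandatory section-Arachis genome structure.

    Section Arachis always receives one A-genome, one B-genome and one
    D-genome diploid species plus the allotetraploid cultivated (AB)
    species; ``species_per_section`` governs the other sections and any
    extra A/B diploid species of section Arachis.
    """
    rng = substream(config.seed, 0)
    accessions: list[Accession] = []
    next_id = 1001

    def draw(rg: tuple[int, int]) -> int:
        lo, hi = rg
        return int(rng.integers(lo, hi + 1))

    def add_species(name: str, section: str, genome: str, ploidy: int,
                    n_acc: int) -> None:
        nonlocal next_id
        for _ in range(n_acc):
            accessions.append(
                Accession(f"ICG {next_id}", name, section, genome, ploidy)
            )
            next_id += 1

    for section in config.sections():
        abbrev = _SECTION_ABBREV.get(section, section[:4].lower())
        k = draw(config.species_per_section)
        if section == "Arachis":
            add_species("A. asim1", section, "A", 20,
                        draw(config.accessions_per_species))
            add_species("A. bsim1", section, "B", 20,
                        draw(config.accessions_per_species))
            add_species("A. dsim1", section, "D", 20,
                        draw(config.accessions_per_species))
            add_species(cultivated_species, section, "AB", 40,
                        config.cultivated_accessions)
            n_a, n_b = 1, 1
            for _ in range(max(0, k - 4)):
                if rng.random() < 0.5:
                    n_a += 1
                    add_species(f"A. asim{n_a}", section, "A", 20,
                                draw(config.accessions_per_species))
                else:
                    n_b += 1
                    add_species(f"A. bsim{n_b}", section, "B", 20,
                                draw(config.accessions_per_species))
        else:
            for j in range(1, k + 1):
                add_species(f"A. {abbrev}{j}", section, "unassigned", 20,
                            draw(config.accessions_per_species))
    taxonomy = Taxonomy(accessions, cultivated_species=cultivated_species)
    if "Arachis" in config.sections():
        if len(taxonomy.accessions_of_species(cultivated_species)) < 2:
            raise ValidationError(
                "config cannot satisfy the tetraploid-species requirement"
            )
    return taxonomy


def generate_marker_panel(config: SimulationConfig) -> MarkerPanel:
    """Panel of genomic ("AhSSR") and genic ("CsSSR") markers."""
    rng = substream(config.seed, 1)
    markers: list[Marker] = []
    for i in range(config.n_genomic_markers):
        lo = int(rng.integers(80, 301))
        hi = lo + int(rng.integers(120, 261))
        markers.append(Marker(f"AhSSR{i + 1:03d}", "genomic", (lo, hi)))
    for i in range(config.n_genic_markers):
        lo = int(rng.integers(80, 301))
        hi = lo + int(rng.integers(120, 261))
        markers.append(Marker(f"CsSSR{i + 1:02d}", "genic", (lo, hi)))
    return MarkerPanel(markers)


# ---------------------------------------------------------------------------
# dataset simulation
# ---------------------------------------------------------------------------

def simulate_dataset(
    taxonomy: Taxonomy,
    panel: MarkerPanel,
    config: SimulationConfig,
) -> tuple[AlleleMatrix, AmplificationMatrix, GroundTruth]:
    """Simulate band calls for every (accession, marker) pair.

    See the module docstring for the generative model.  Everything is
    reproducible from ``config.seed``; per-cell draws use counter-keyed RNG
    sub-streams so enlarging the panel or germplasm never perturbs earlier
    draws.
    """
    a_species = [
        s for s in taxonomy.species_present()
        if taxonomy.accessions_of_species(s)[0].genome == "A"
        and taxonomy.accessions_of_species(s)[0].ploidy < 40
    ]
    b_species = [
        s for s in taxonomy.species_present()
        if taxonomy.accessions_of_species(s)[0].genome == "B"
        and taxonomy.accessions_of_species(s)[0].ploidy < 40
    ]
    if not a_species or not b_species:
        raise ValidationError(
            "taxonomy must contain at least one A-genome and one B-genome "
            "diploid species"
        )
    donor_A = taxonomy.accessions_of_species(a_species[0])[0].accession_id
    donor_B = taxonomy.accessions_of_species(b_species[0])[0].accession_id

    diploid_accs = [a for a in taxonomy.accessions if a.ploidy < 40]
    tetraploid_accs = taxonomy.tetraploids()
    diploid_species = []
    for a in diploid_accs:
        if a.species not in diploid_species:
            diploid_species.append(a.species)
    sections_present = taxonomy.sections_present()
    seed = config.seed

    # genotype: accession_id -> marker_id -> set of sizes (python ints)
    geno: dict[str, dict[str, set[int]]] = {
        a.accession_id: {} for a in taxonomy.accessions
    }
    species_pool: dict[tuple[str, str], set[int]] = {}
    used_sizes: dict[str, set[int]] = {}
    global_pool: dict[str, list[int]] = {}

    # -- allele pools ------------------------------------------------------
    for mi, marker in enumerate(panel.markers):
        rng_m = substream(seed, 10, mi)
        lo_k, hi_k = config.alleles_per_marker
        lo_w, hi_w = marker.size_window
        window = np.arange(lo_w, hi_w + 1)
        k = min(int(rng_m.integers(lo_k, hi_k + 1)), len(window))
        pool = sorted(int(s) for s in rng_m.choice(window, size=k, replace=False))
        global_pool[marker.marker_id] = pool
        used_sizes[marker.marker_id] = set(pool)
        shared: list[int] = []
        exclusive: dict[str, list[int]] = {s: [] for s in sections_present}
        for size in pool:
            if rng_m.random() < config.section_exclusive_frac:
                sec = sections_present[int(rng_m.integers(len(sections_present)))]
                exclusive[sec].append(size)
            else:
                shared.append(size)
        section_pool = {
            sec: shared + exclusive[sec] for sec in sections_present
        }
        for si, sp in enumerate(diploid_species):
            rng_s = substream(seed, 11, mi, si)
            sec = taxonomy.section_of_species(sp)
            pool_sec = section_pool[sec]
            chosen = [
                s for s in pool_sec
                if rng_s.random() < config.species_pool_frac
            ]
            if not chosen:
                source = pool_sec if pool_sec else pool
                chosen = [source[int(rng_s.integers(len(source)))]]
            species_pool[(sp, marker.marker_id)] = set(chosen)

    # -- diploid band calls ------------------------------------------------
    acc_index = {a.accession_id: i for i, a in enumerate(taxonomy.accessions)}
    for acc in diploid_accs:
        rank = config.divergence_rank(acc.section)
        decay = max(0.0, 1.0 - config.section_divergence_penalty * rank)
        for mi, marker in enumerate(panel.markers):
            rng_a = substream(seed, 12, mi, acc_index[acc.accession_id])
            p = config.base_transfer_prob[marker.source_class] * decay
            if rng_a.random() >= p:
                continue
            pool = sorted(species_pool[(acc.species, marker.marker_id)])
            mask = rng_a.random(len(pool)) < config.allele_presence_prob
            carried = [s for s, m in zip(pool, mask) if m]
            if not carried:
                carried = [pool[int(rng_a.integers(len(pool)))]]
            geno[acc.accession_id][marker.marker_id] = set(carried)

    # -- planted species-private alleles -----------------------------------
    private: dict[str, set[Allele]] = {}
    for mi, marker in enumerate(panel.markers):
        lo_w, hi_w = marker.size_window
        for si, sp in enumerate(diploid_species):
            rng_p = substream(seed, 13, mi, si)
            if rng_p.random() >= config.p_private_allele:
                continue
            carriers = [
                a.accession_id for a in taxonomy.accessions_of_species(sp)
                if geno[a.accession_id].get(marker.marker_id)
            ]
            if not carriers:
                continue
            size = _fresh_size(rng_p, lo_w, hi_w, used_sizes[marker.marker_id])
            if size is None:
                continue
            mask = rng_p.random(len(carriers)) < config.allele_presence_prob
            holders = [a for a, m in zip(carriers, mask) if m] or [carriers[0]]
            for a in holders:
                geno[a][marker.marker_id].add(size)
            private.setdefault(sp, set()).add(Allele(marker.marker_id, size))

    # -- cleanup: no accidental single-species alleles among diploids ------
    # Guarantees that the species-specific alleles of the diploid view are
    # exactly the planted private ones (precision = recall = 1 for the
    # detector).  Accidental singletons gain one extra carrier from another
    # species — pool holders first, then the same section, then anywhere —
    # or are dropped when no other accession amplified the marker.
    private_keys = {
        (al.marker_id, al.size_bp) for als in private.values() for al in als
    }
    for mi, marker in enumerate(panel.markers):
        mid = marker.marker_id
        rng_c = substream(seed, 14, mi)
        carrier_map: dict[int, list[str]] = {}
        for acc in diploid_accs:
            for size in geno[acc.accession_id].get(mid, ()):
                carrier_map.setdefault(size, []).append(acc.accession_id)
        for size in sorted(carrier_map):
            if (mid, size) in private_keys:
                continue
            carriers = carrier_map[size]
            species = {taxonomy[a].species for a in carriers}
            if len(species) != 1:
                continue
            sp0 = next(iter(species))
            sec0 = taxonomy.section_of_species(sp0)
            amplified_others = [
                a for a in diploid_accs
                if a.species != sp0 and geno[a.accession_id].get(mid)
            ]
            tiers = (
                [a for a in amplified_others
                 if size in species_pool[(a.species, mid)]],
                [a for a in amplified_others if a.section == sec0],
                amplified_others,
            )
            chosen = None
            for tier in tiers:
                if tier:
                    chosen = tier[int(rng_c.integers(len(tier)))]
                    break
            if chosen is not None:
                geno[chosen.accession_id][mid].add(size)
            else:
                for a in carriers:
                    geno[a][mid].discard(size)
                    if not geno[a][mid]:
                        del geno[a][mid]

    # -- tetraploids: thinned union of the two donors ----------------------
    donor_sets = {
        d: {m: set(s) for m, s in geno[d].items()} for d in (donor_A, donor_B)
    }
    for ti, tet in enumerate(tetraploid_accs):
        rng_t = substream(seed, 15, ti)
        for mid in panel.ids():
            union = sorted(
                donor_sets[donor_A].get(mid, set())
                | donor_sets[donor_B].get(mid, set())
            )
            kept = {
                s for s in union if rng_t.random() < config.donor_retention
            }
            if kept:
                geno[tet.accession_id][mid] = kept

    # -- duplicated loci: tetraploid-only extra fragments ------------------
    rng_d = substream(seed, 16)
    duplicated: set[str] = set()
    tet_only: set[Allele] = set()
    if tetraploid_accs:
        for marker in panel.of_class("genomic"):
            mid = marker.marker_id
            if not donor_sets[donor_A].get(mid) or not donor_sets[donor_B].get(mid):
                continue
            if rng_d.random() >= config.p_tetraploid_locus:
                continue
            lo_w, hi_w = marker.size_window
            size = _fresh_size(rng_d, lo_w, hi_w, used_sizes[mid])
            if size is None:
                continue
            duplicated.add(mid)
            tet_only.add(Allele(mid, size))
            anchor = tetraploid_accs[0].accession_id
            for tet in tetraploid_accs:
                geno[tet.accession_id].setdefault(mid, set()).add(size)
            # anchor the full signature: one allele from each donor subgenome
            geno[anchor][mid].add(min(donor_sets[donor_A][mid]))
            geno[anchor][mid].add(min(donor_sets[donor_B][mid]))

    # -- safety floor: every accession shows at least one band -------------
    first = panel.markers[0]
    for acc in taxonomy.accessions:
        if not any(geno[acc.accession_id].values()):
            if acc.ploidy < 40:
                fallback = sorted(species_pool[(acc.species, first.marker_id)])
            else:
                fallback = global_pool[first.marker_id]
            geno[acc.accession_id][first.marker_id] = {fallback[0]}

    # -- assemble matrices -------------------------------------------------
    allele_carriers: dict[Allele, set[str]] = {}
    for acc in taxonomy.accessions:
        for mid, sizes in geno[acc.accession_id].items():
            for size in sizes:
                allele_carriers.setdefault(
                    Allele(mid, size), set()
                ).add(acc.accession_id)
    marker_order = {m: i for i, m in enumerate(panel.ids())}
    alleles = sorted(
        allele_carriers, key=lambda al: (marker_order[al.marker_id], al.size_bp)
    )
    acc_ids = taxonomy.ids()
    cells = np.zeros((len(alleles), len(acc_ids)), dtype=bool)
    for i, al in enumerate(alleles):
        for a in allele_carriers[al]:
            cells[i, acc_index[a]] = True
    mat = AlleleMatrix(alleles, acc_ids, cells)
    amp = mat.to_amplification(panel)

    # -- ground-truth ledger ------------------------------------------------
    section_specific: dict[str, set[Allele]] = {}
    for al, carriers in allele_carriers.items():
        secs = {taxonomy[a].section for a in carriers}
        if len(secs) == 1:
            section_specific.setdefault(secs.pop(), set()).add(al)
    truth = GroundTruth(
        donor_A=donor_A,
        donor_B=donor_B,
        private_alleles=private,
        section_specific_alleles=section_specific,
        tetraploid_only_alleles=tet_only,
        duplicated_locus_markers=duplicated,
    )
    return mat, amp, truth


def _fresh_size(rng: np.random.Generator, lo: int, hi: int,
                used: set[int]) -> int | None:
    """A size in [lo, hi] not yet used at this marker; None when exhausted."""
    free = [s for s in range(lo, hi + 1) if s not in used]
    if not free:
        return None
    size = free[int(rng.integers(len(free)))]
    used.add(size)
    return size


def simulate(config: SimulationConfig) -> tuple[
    Taxonomy, MarkerPanel, AlleleMatrix, AmplificationMatrix, GroundTruth
]:
    """Convenience wrapper: taxonomy + panel + dataset from one config."""
    taxonomy = generate_taxonomy(config)
    panel = generate_marker_panel(config)
    mat, amp, truth = simulate_dataset(taxonomy, panel, config)
    return taxonomy, panel, mat, amp, truth


def config_with_seed(config: SimulationConfig, seed: int) -> SimulationConfig:
    """Copy of ``config`` with a different seed (kept below 2**31)."""
    return replace(config, seed=int(seed) % (2 ** 31))
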