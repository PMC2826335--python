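"""Genome-donor inference for the allotetraploid by group genetic distance.

An allotetraploid (AABB) carries both diploid subgenomes, so the diploid
accessions closest to the tetraploid group in Nei-Li distance are the best
candidates for its A- and B-genome donors.  "Distance to the group" is the
arithmetic mean of the pairwise distances to every group member —
parameter-free, unlike a consensus-profile construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .errors import ValidationError
from .model import AlleleMatrix, Taxonomy
from .phylogeny import nei_li_distance
from .simulate import SimulationConfig, config_with_seed, simulate

DONOR_GENOMES = ("A", "B")


def group_distance(accession: str, group: list[str], mat: AlleleMatrix) -> float:
    """Mean Nei-Li distance from one accession to each member of a group."""
    if not group:
        raise ValidationError("group must be non-empty")
    if len(set(group)) != len(group):
        raise ValidationError("group contains duplicate accession ids")
    if accession in group:
        raise ValidationError(
            f"accession {accession!r} must not be a member of the group"
        )
    x = mat.profile(accession)
    total = 0.0
    for g in group:
        total += nei_li_distance(x, mat.profile(g))
    return total / len(group)


@dataclass
class DonorReport:
    """Ranked diploid donor candidates, one list per genome class.

    ``rankings[genome]`` columns: accession_id, species, genome,
    group_distance — sorted ascending, ties broken by accession id.  The
    head of each list is the nominated donor.
    """

    target_species: str
    rankings: dict[str, pd.DataFrame]

    def nominated(self, genome: str) -> str:
        frame = self.rankings[genome]
        return str(frame.iloc[0].accession_id)

    def to_frame(self) -> pd.DataFrame:
        return pd.concat(
            [self.rankings[g] for g in DONOR_GENOMES], ignore_index=True
        )


def rank_donor_candidates(
    mat: AlleleMatrix, taxonomy: Taxonomy, target_species: str
) -> DonorReport:
    """Rank A- and B-genome diploids by distance to the target group.

    Candidates are the diploid (2n=20) accessions of genome classes A and B
    within section Arachis; the target group is every accession of
    ``target_species`` present in the matrix.
    """
    present = set(mat.accessions)
    group = [
        a.accession_id
        for a in taxonomy.accessions_of_species(target_species)
        if a.accession_id in present
    ]
    if not group:
        raise ValidationError(
            f"target species {target_species!r} has no accessions in the matrix"
        )
    rankings: dict[str, pd.DataFrame] = {}
    for genome in DONOR_GENOMES:
        rows = []
        for acc in taxonomy.accessions:
            if (
                acc.genome == genome
                and acc.ploidy == 20
                and acc.section == "Arachis"
                and acc.accession_id in present
                and acc.accession_id not in group
            ):
                rows.append(
                    {
                        "accession_id": acc.accession_id,
                        "species": acc.species,
                        "genome": genome,
                        "group_distance": group_distance(
                            acc.accession_id, group, mat
                        ),
                    }
                )
        if not rows:
            raise ValidationError(
                f"no diploid {genome}-genome candidates available"
            )
        frame = pd.DataFrame(rows).sort_values(
            ["group_distance", "accession_id"], kind="stable"
        ).reset_index(drop=True)
        rankings[genome] = frame
    return DonorReport(target_species, rankings)


def donor_recovery_experiment(
    config: SimulationConfig, n_seeds: int
) -> dict[str, float]:
    """Fraction of simulations nominating the true donors, per genome class.

    Each replicate re-simulates taxonomy, panel and genotypes under
    ``config`` with seed ``config.seed + i`` and checks whether the ranked
    candidate lists put the planted donors first.
    """
    if n_seeds < 1:
        raise ValidationError("n_seeds must be >= 1")
    hits = {"A": 0, "B": 0}
    for i in range(n_seeds):
        cfg = config_with_seed(config, config.seed + i)
        taxonomy, _, mat, _, truth = simulate(cfg)
        report = rank_donor_candidates(mat, taxonomy, taxonomy.cultivated_species)
        if report.nominated("A") == truth.donor_A:
            hits["A"] += 1
        if report.nominated("B") == truth.donor_B:
            hits["B"] += 1
    return {g: hits[g] / n_seeds for g in DONOR_GENOMES}
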