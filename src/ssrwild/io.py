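"""Delimited-text readers/writers for taxonomies, panels and genotype tables.

All tables are tab- or comma-delimited with headers; the dialect is sniffed
on read and written as TSV.  Genotype data travel in long format —
``accession_id, marker_id, size_bp, presence`` — and absent rows mean a 0
score, never missing data.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ValidationError
from .model import (
    Accession,
    Allele,
    AlleleMatrix,
    AmplificationMatrix,
    Marker,
    MarkerPanel,
    Taxonomy,
    check_amplification_consistency,
)

_TAXONOMY_COLUMNS = ["accession_id", "species", "section", "genome", "ploidy"]
_PANEL_COLUMNS = ["marker_id", "source_class", "size_min", "size_max"]
_GENOTYPE_COLUMNS = ["accession_id", "marker_id", "size_bp", "presence"]


def _read_table(path, required: list[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"file not found: {path}")
    try:
        frame = pd.read_csv(path, sep=None, engine="python", dtype=str,
                            skip_blank_lines=True)
    except Exception as exc:
        raise ValidationError(f"cannot parse {path}: {exc}") from exc
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise ValidationError(
            f"{path}: missing required columns {missing}; found "
            f"{list(frame.columns)}"
        )
    return frame


def read_taxonomy(path) -> Taxonomy:
    """Read and validate an accession table."""
    frame = _read_table(path, _TAXONOMY_COLUMNS)
    accessions = []
    for _, row in frame.iterrows():
        try:
            ploidy = int(row.ploidy)
        except (TypeError, ValueError):
            raise ValidationError(
                f"non-integer ploidy {row.ploidy!r} for accession "
                f"{row.accession_id!r}"
            ) from None
        accessions.append(
            Accession(
                accession_id=str(row.accession_id),
                species=str(row.species),
                section=str(row.section),
                genome=str(row.genome),
                ploidy=ploidy,
                country=str(row.get("country", "") or ""),
            )
        )
    return Taxonomy(accessions)


def write_taxonomy(taxonomy: Taxonomy, path) -> None:
    frame = pd.DataFrame(
        [
            {
                "accession_id": a.accession_id,
                "species": a.species,
                "section": a.section,
                "genome": a.genome,
                "ploidy": a.ploidy,
                "country": a.country,
            }
            for a in taxonomy.accessions
        ]
    )
    frame.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_marker_panel(path) -> MarkerPanel:
    frame = _read_table(path, _PANEL_COLUMNS)
    markers = []
    for _, row in frame.iterrows():
        try:
            lo, hi = int(row.size_min), int(row.size_max)
        except (TypeError, ValueError):
            raise ValidationError(
                f"non-integer size window for marker {row.marker_id!r}"
            ) from None
        markers.append(Marker(str(row.marker_id), str(row.source_class), (lo, hi)))
    return MarkerPanel(markers)


def write_marker_panel(panel: MarkerPanel, path) -> None:
    frame = pd.DataFrame(
        [
            {
                "marker_id": m.marker_id,
                "source_class": m.source_class,
                "size_min": m.size_window[0],
                "size_max": m.size_window[1],
            }
            for m in panel.markers
        ]
    )
    frame.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_genotype_long(
    path, panel: MarkerPanel, taxonomy: Taxonomy
) -> tuple[AlleleMatrix, AmplificationMatrix]:
    """Read long-format band calls into the two companion matrices.

    Every id must resolve against the panel and taxonomy, and every size
    must fall inside the marker's size window.  Accessions without any
    positive row get all-absent columns; the amplification matrix is
    derived as the any-allele-present reduction and cross-checked.
    """
    frame = _read_table(path, _GENOTYPE_COLUMNS)
    carriers: dict[Allele, set[str]] = {}
    for _, row in frame.iterrows():
        acc = str(row.accession_id)
        mid = str(row.marker_id)
        if acc not in taxonomy:
            raise ValidationError(f"unknown accession_id {acc!r} in genotype table")
        if mid not in panel:
            raise ValidationError(f"unknown marker_id {mid!r} in genotype table")
        try:
            size = int(row.size_bp)
            presence = int(row.presence)
        except (TypeError, ValueError):
            raise ValidationError(
                f"non-integer size/presence in genotype row for ({acc}, {mid})"
            ) from None
        if presence not in (0, 1):
            raise ValidationError(
                f"presence must be 0 or 1, got {presence} for ({acc}, {mid})"
            )
        if not panel[mid].contains_size(size):
            raise ValidationError(
                f"size {size} bp outside the size window "
                f"{panel[mid].size_window} of marker {mid!r}"
            )
        if presence:
            carriers.setdefault(Allele(mid, size), set()).add(acc)
    marker_order = {m: i for i, m in enumerate(panel.ids())}
    alleles = sorted(
        carriers, key=lambda al: (marker_order[al.marker_id], al.size_bp)
    )
    acc_ids = taxonomy.ids()
    acc_index = {a: j for j, a in enumerate(acc_ids)}
    cells = np.zeros((len(alleles), len(acc_ids)), dtype=bool)
    for i, al in enumerate(alleles):
        for a in carriers[al]:
            cells[i, acc_index[a]] = True
    mat = AlleleMatrix(alleles, acc_ids, cells)
    amp = mat.to_amplification(panel)
    check_amplification_consistency(amp, mat)
    return mat, amp


def write_genotype_long(mat: AlleleMatrix, path) -> None:
    """Write the positive band calls of an allele matrix in long format."""
    rows = []
    for i, al in enumerate(mat.alleles):
        for j in np.flatnonzero(mat.cells[i]):
            rows.append(
                {
                    "accession_id": mat.accessions[j],
                    "marker_id": al.marker_id,
                    "size_bp": al.size_bp,
                    "presence": 1,
                }
            )
    frame = pd.DataFrame(rows, columns=_GENOTYPE_COLUMNS)
    frame = frame.sort_values(
        ["accession_id", "marker_id", "size_bp"], kind="stable"
    )
    frame.to_csv(path, sep="\t", index=False, lineterminator="\n")


def write_report(tables: Mapping[str, pd.DataFrame], path) -> list[Path]:
    """Write one TSV per named table plus a JSON summary, deterministically.

    Rows are sorted by every column left-to-right so repeated runs on the
    same inputs produce byte-identical files.
    """
    outdir = Path(path)
    try:
        outdir.mkdir(parents=True, exist_ok=True)
        probe = outdir / ".write_probe"
        probe.touch()
        probe.unlink()
    except OSError as exc:
        raise ValidationError(f"cannot write to directory {outdir}: {exc}") from exc
    written: list[Path] = []
    summary: dict[str, dict] = {}
    for name in sorted(tables):
        frame = tables[name]
        if len(frame):
            frame = frame.sort_values(list(frame.columns), kind="stable")
        target = outdir / f"{name}.tsv"
        frame.to_csv(target, sep="\t", index=False, lineterminator="\n")
        written.append(target)
        summary[name] = {
            "n_rows": int(len(frame)),
            "columns": [str(c) for c in frame.columns],
        }
    summary_path = outdir / "report_summary.json"
    with open(summary_path, "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    written.append(summary_path)
    return written
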