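"""Readers and writers for the tab-delimited formats the pipeline touches.

Three formats, all UTF-8 TSV with a header row; empty cells or "." mean
missing:

* long-form mutation calls: ``sample_id  gene  [vaf]``
* binary mutation matrix: first column ``sample_id``, one column per gene
* clinical table: ``sample_id  response  os_months  os_event  ipssr  therapy``
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .cohort import (
    ClinicalRecord,
    Cohort,
    CohortError,
    GenePanel,
    MutationProfile,
)

__all__ = [
    "read_mutation_long",
    "write_mutation_long",
    "read_binary_matrix",
    "write_binary_matrix",
    "read_clinical",
    "write_clinical",
    "assemble_cohort",
    "write_cohort",
    "read_cohort",
]

_MISSING = {"", "."}


class ParseError(CohortError):
    """A malformed input row; the message names the offending line."""


def _is_missing(cell: str) -> bool:
    return cell is None or cell.strip() in _MISSING


def read_mutation_long(
    path, panel: Optional[GenePanel] = None
) -> tuple[list[MutationProfile], GenePanel]:
    """Read long-form mutation calls into profiles.

    One row per (sample, mutated gene).  Duplicate rows collapse to a single
    mutated status, retaining the maximum VAF.  When ``panel`` is given, rows
    naming a gene outside it are rejected; otherwise the panel is inferred
    from the observed genes (sorted lexicographically).  Samples listed with
    no valid rows do not appear; zero-mutation samples must be carried via
    the binary-matrix format or the clinical table join.
    """
    path = Path(path)
    per_sample: dict[str, dict[str, Optional[float]]] = {}
    order: list[str] = []
    observed_genes: set[str] = set()
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise ParseError(f"{path}: empty file") from None
        header = [h.strip().lower() for h in header]
        if header[:2] != ["sample_id", "gene"]:
            raise ParseError(
                f"{path}: expected header starting 'sample_id\\tgene', got {header}"
            )
        has_vaf = len(header) > 2 and header[2] == "vaf"
        for lineno, row in enumerate(reader, start=2):
            if not row or all(_is_missing(c) for c in row):
                continue
            if len(row) < 2:
                raise ParseError(f"{path}:{lineno}: expected >= 2 columns")
            sample = row[0].strip()
            gene = row[1].strip().upper()
            if not sample or not gene:
                raise ParseError(f"{path}:{lineno}: empty sample_id or gene")
            if panel is not None and gene not in panel:
                raise ParseError(
                    f"{path}:{lineno}: gene {gene!r} not in the supplied panel"
                )
            vaf: Optional[float] = None
            if has_vaf and len(row) > 2 and not _is_missing(row[2]):
                try:
                    vaf = float(row[2])
                except ValueError:
                    raise ParseError(
                        f"{path}:{lineno}: VAF {row[2]!r} is not a number"
                    ) from None
                if not (0.0 <= vaf <= 1.0):
                    raise ParseError(
                        f"{path}:{lineno}: VAF {vaf} outside [0, 1]"
                    )
            if sample not in per_sample:
                per_sample[sample] = {}
                order.append(sample)
            prev = per_sample[sample].get(gene)
            if gene in per_sample[sample]:
                # duplicate (sample, gene): keep max VAF
                if vaf is not None and (prev is None or vaf > prev):
                    per_sample[sample][gene] = vaf
            else:
                per_sample[sample][gene] = vaf
            observed_genes.add(gene)
    resolved = panel if panel is not None else GenePanel(sorted(observed_genes))
    profiles = [MutationProfile(s, per_sample[s]) for s in order]
    return profiles, resolved


def write_mutation_long(path, profiles: Sequence[MutationProfile]) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["sample_id", "gene", "vaf"])
        for p in profiles:
            for gene in sorted(p.mutations):
                vaf = p.mutations[gene]
                w.writerow([p.sample_id, gene, "." if vaf is None else repr(vaf)])


def read_binary_matrix(path) -> tuple[list[MutationProfile], GenePanel]:
    """Read a patient x gene 0/1 matrix; round-trips with write_binary_matrix."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.columns[0] != "sample_id":
        raise ParseError(f"{path}: first column must be 'sample_id'")
    panel = GenePanel(list(df.columns[1:]))
    profiles = []
    for i, row in df.iterrows():
        muts: dict[str, Optional[float]] = {}
        for gene in df.columns[1:]:
            cell = str(row[gene]).strip()
            if cell not in {"0", "1"}:
                raise ParseError(
                    f"{path}: row {i + 2}: non-binary cell {row[gene]!r} "
                    f"for gene {gene}"
                )
            if cell == "1":
                muts[gene.upper()] = None
        profiles.append(MutationProfile(str(row["sample_id"]), muts))
    return profiles, panel


def write_binary_matrix(path, cohort_or_profiles, panel: Optional[GenePanel] = None) -> None:
    if isinstance(cohort_or_profiles, Cohort):
        profiles = cohort_or_profiles.profiles
        panel = cohort_or_profiles.panel
    else:
        profiles = cohort_or_profiles
        if panel is None:
            raise CohortError("panel required when writing bare profiles")
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["sample_id", *panel])
        for p in profiles:
            w.writerow([p.sample_id, *(int(p.has(g)) for g in panel)])


_CLINICAL_COLS = ["sample_id", "response", "os_months", "os_event", "ipssr", "therapy"]


def read_clinical(path) -> list[ClinicalRecord]:
    path = Path(path)
    records = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        missing_cols = set(_CLINICAL_COLS) - set(reader.fieldnames or [])
        if missing_cols:
            raise ParseError(f"{path}: missing columns {sorted(missing_cols)}")
        for lineno, row in enumerate(reader, start=2):
            try:
                resp = (
                    ClinicalRecord.parse_response(row["response"])
                    if not _is_missing(row["response"])
                    else None
                )
                os_months = (
                    float(row["os_months"])
                    if not _is_missing(row["os_months"])
                    else None
                )
                os_event = (
                    int(row["os_event"]) if not _is_missing(row["os_event"]) else None
                )
                ipssr = (
                    ClinicalRecord.parse_ipssr(row["ipssr"])
                    if not _is_missing(row["ipssr"])
                    else None
                )
                therapy = (
                    ClinicalRecord.parse_therapy(row["therapy"])
                    if not _is_missing(row["therapy"])
                    else None
                )
                rec = ClinicalRecord(
                    sample_id=row["sample_id"].strip(),
                    response=resp if resp is not None else ClinicalRecord.parse_response("UNKNOWN"),
                    os_months=os_months,
                    os_event=os_event,
                    ipssr=ipssr if ipssr is not None else ClinicalRecord.parse_ipssr("UNKNOWN"),
                    therapy=therapy if therapy is not None else ClinicalRecord.parse_therapy("UNKNOWN"),
                )
            except (CohortError, ValueError) as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from None
            records.append(rec)
    return records


def write_clinical(path, clinical: Sequence[ClinicalRecord]) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(_CLINICAL_COLS)
        for c in clinical:
            w.writerow(
                [
                    c.sample_id,
                    c.response.value,
                    "." if c.os_months is None else repr(float(c.os_months)),
                    "." if c.os_event is None else int(c.os_event),
                    c.ipssr.value,
                    c.therapy.value,
                ]
            )


def assemble_cohort(
    profiles: Sequence[MutationProfile],
    clinical: Sequence[ClinicalRecord],
    panel: GenePanel,
) -> tuple[Cohort, list[str]]:
    """Inner-join profiles and clinical records on sample_id.

    Returns the cohort plus the sorted ids present in only one input (these
    are dropped).  Zero overlap is an error.
    """
    prof_ids = {p.sample_id for p in profiles}
    clin_ids = {c.sample_id for c in clinical}
    shared = prof_ids & clin_ids
    if not shared:
        raise CohortError("no overlapping sample_ids between profiles and clinical")
    dropped = sorted(prof_ids ^ clin_ids)
    cohort = Cohort(
        panel,
        [p for p in profiles if p.sample_id in shared],
        [c for c in clinical if c.sample_id in shared],
    )
    return cohort, dropped


def write_cohort(outdir, cohort: Cohort, prefix: str = "cohort") -> dict[str, Path]:
    """Write the three cohort TSVs (matrix, long-form VAFs, clinical)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": outdir / f"{prefix}_mutations.tsv",
        "long": outdir / f"{prefix}_mutations_long.tsv",
        "clinical": outdir / f"{prefix}_clinical.tsv",
    }
    write_binary_matrix(paths["matrix"], cohort)
    write_mutation_long(paths["long"], cohort.profiles)
    write_clinical(paths["clinical"], cohort.clinical)
    return paths


def read_cohort(matrix_path, clinical_path) -> Cohort:
    profiles, panel = read_binary_matrix(matrix_path)
    clinical = read_clinical(clinical_path)
    cohort, _ = assemble_cohort(profiles, clinical, panel)
    return cohort
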