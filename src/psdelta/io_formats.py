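"""Readers and writers for the external formats the pipeline touches.

All readers validate strictly and raise rather than silently repairing
malformed input. Protein coordinates are 1-based inclusive at every
interface boundary.

Formats:

* FASTA — protein sequences (via Biopython); UniProt-style ``sp|ACC|NAME``
  headers yield the accession token.
* mutation TSV — a minimal seven-column missense-mutation table
  (``sample``, ``gene``, ``accession``, ``position``, ``ref``, ``alt``,
  ``cancer_type``); a column-mapping dict lets MAF-like exports be ingested.
* GMT — annotation gene sets (kinase substrates, TF targets, pathways).
* clinical TSV — survival time/event plus age, sex, TMB, stage covariates.
* effects TSV — the per-mutation delta-PS output table; round-trips
  losslessly through :func:`read_effects_table`.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
from Bio import SeqIO

from .errors import InputError, ValidationError

logger = logging.getLogger(__name__)

#: The 20 standard amino-acid one-letter codes.
STANDARD_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Nonstandard/ambiguous letters seen in real proteomes (rejected by default).
NONSTANDARD_AA = frozenset("BJOUXZ")


@dataclass(frozen=True)
class ProteinRecord:
    """An accession plus its amino-acid sequence (uppercase, standard letters)."""

    accession: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValidationError(f"protein {self.accession!r}: empty sequence")
        bad = set(self.sequence) - STANDARD_AA
        if bad:
            raise ValidationError(
                f"protein {self.accession!r}: disallowed letter(s) "
                f"{''.join(sorted(bad))!r} in sequence"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class MissenseMutation:
    """A single-residue substitution on a protein, 1-based position."""

    sample_id: str
    gene: str
    accession: str
    position: int
    ref_aa: str
    alt_aa: str
    cancer_type: str

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValidationError(
                f"mutation {self.gene} {self.ref_aa}{self.position}{self.alt_aa}: "
                "position must be >= 1"
            )

    @property
    def hgvs_p(self) -> str:
        return f"p.{self.ref_aa}{self.position}{self.alt_aa}"

    def key(self) -> tuple:
        """Identity of the protein change (sample-independent)."""
        return (self.accession, self.position, self.ref_aa, self.alt_aa)


@dataclass(frozen=True)
class AnnotationSetCollection:
    """Named gene sets (e.g. kinase substrates, TF targets, pathways)."""

    sets: Mapping[str, frozenset[str]]

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValidationError(f"annotation set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())


@dataclass(frozen=True)
class ClinicalRecord:
    """Per-patient survival outcome and covariates.

    ``stage`` is ordinal (1..4) or None when missing; ``sex`` is 0/1 coded.
    """

    sample_id: str
    time: float
    event: int
    age: float
    sex: int
    tmb: float
    stage: int | None = None
    cancer_type: str = ""

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValidationError(f"clinical {self.sample_id}: time < 0")
        if self.event not in (0, 1):
            raise ValidationError(f"clinical {self.sample_id}: event not in {{0,1}}")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def _accession_from_header(header: str) -> str:
    token = header.split()[0]
    # UniProt convention: db|ACCESSION|ENTRY_NAME
    if "|" in token:
        parts = token.split("|")
        if len(parts) >= 2 and parts[1]:
            return parts[1]
    return token


def read_fasta(
    path: str | Path,
    *,
    permissive: bool = False,
    replacement: str = "A",
) -> list[ProteinRecord]:
    """Read protein records from a FASTA file.

    Accessions come from the first header token (UniProt ``sp|ACC|NAME``
    headers yield ``ACC``); sequences are uppercased. Duplicate accessions,
    empty sequences and disallowed letters are errors. With
    ``permissive=True`` the ambiguous letters B/J/O/U/X/Z are mapped to
    ``replacement`` (logged per record) instead of rejected.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"FASTA file not found: {path}")
    if replacement not in STANDARD_AA:
        raise ValidationError(f"replacement letter {replacement!r} is not standard")

    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        accession = _accession_from_header(entry.description or entry.id)
        if accession in seen:
            raise ValidationError(f"duplicate accession {accession!r} in {path}")
        seen.add(accession)
        seq = str(entry.seq).upper()
        nonstd = set(seq) & NONSTANDARD_AA
        if nonstd and permissive:
            for letter in sorted(nonstd):
                seq = seq.replace(letter, replacement)
            logger.info(
                "record %s: mapped nonstandard letter(s) %s -> %s",
                accession, "".join(sorted(nonstd)), replacement,
            )
        records.append(ProteinRecord(accession=accession, sequence=seq))
    return records


def write_fasta(records: Sequence[ProteinRecord], path: str | Path, width: int = 60) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for rec in records:
            fh.write(f">{rec.accession}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Mutation table
# ---------------------------------------------------------------------------

MUTATION_COLUMNS = ("sample", "gene", "accession", "position", "ref", "alt", "cancer_type")


def read_mutation_table(
    path: str | Path,
    *,
    column_map: Mapping[str, str] | None = None,
) -> list[MissenseMutation]:
    """Read a seven-column missense-mutation TSV.

    Rows whose ref and alt residues are equal are not missense and are
    dropped with a logged count. Exact duplicate rows (all seven fields
    equal) are collapsed to one; the number removed is logged — the same
    duplication-filtering contract a cohort-level mutation export needs.

    ``column_map`` maps required names to the file's actual column names,
    so MAF-like exports can be ingested without rewriting headers.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"mutation table not found: {path}")
    df = pd.read_csv(path, sep="\t", dtype=str)
    if column_map:
        df = df.rename(columns={v: k for k, v in column_map.items()})
    missing = [c for c in MUTATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(
            f"mutation table {path}: missing required column(s) {missing}"
        )
    df = df[list(MUTATION_COLUMNS)]

    n_before = len(df)
    df = df.drop_duplicates(keep="first")
    n_dups = n_before - len(df)
    if n_dups:
        logger.info("mutation table %s: removed %d exact duplicate row(s)", path, n_dups)

    mutations: list[MissenseMutation] = []
    n_not_missense = 0
    for idx, row in enumerate(df.itertuples(index=False), start=1):
        if row.ref == row.alt:
            n_not_missense += 1
            continue
        try:
            position = int(row.position)
        except (TypeError, ValueError):
            raise ValidationError(
                f"mutation table {path}: unparseable position {row.position!r} "
                f"at data row {idx}"
            ) from None
        mutations.append(
            MissenseMutation(
                sample_id=row.sample,
                gene=row.gene,
                accession=row.accession,
                position=position,
                ref_aa=row.ref,
                alt_aa=row.alt,
                cancer_type=row.cancer_type,
            )
        )
    if n_not_missense:
        logger.info(
            "mutation table %s: dropped %d non-missense row(s) (ref == alt)",
            path, n_not_missense,
        )
    return mutations


def write_mutation_table(mutations: Sequence[MissenseMutation], path: str | Path) -> None:
    rows = [
        {
            "sample": m.sample_id,
            "gene": m.gene,
            "accession": m.accession,
            "position": m.position,
            "ref": m.ref_aa,
            "alt": m.alt_aa,
            "cancer_type": m.cancer_type,
        }
        for m in mutations
    ]
    pd.DataFrame(rows, columns=list(MUTATION_COLUMNS)).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# GMT
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path) -> AnnotationSetCollection:
    """Read a GMT file: set name, description, then tab-separated members.

    The description column is ignored; duplicate members within a set are
    stored once; a repeated set name is ambiguous and raises.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"GMT file not found: {path}")
    sets: dict[str, frozenset[str]] = {}
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValidationError(
                    f"GMT {path} line {lineno}: expected >= 3 tab-separated "
                    f"fields, got {len(fields)}"
                )
            name = fields[0]
            if name in sets:
                raise ValidationError(
                    f"GMT {path} line {lineno}: duplicate set name {name!r}"
                )
            members = frozenset(m for m in fields[2:] if m)
            if not members:
                raise ValidationError(f"GMT {path} line {lineno}: set {name!r} empty")
            sets[name] = members
    return AnnotationSetCollection(sets=sets)


def write_gmt(collection: AnnotationSetCollection, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for name, members in collection:
            fh.write("\t".join([name, "na", *sorted(members)]) + "\n")


# ---------------------------------------------------------------------------
# Clinical table
# ---------------------------------------------------------------------------

CLINICAL_COLUMNS = ("sample", "time", "event", "age", "sex", "tmb", "stage", "cancer_type")


def read_clinical_table(path: str | Path) -> list[ClinicalRecord]:
    """Read a clinical TSV with survival outcome and covariates.

    ``stage`` may be blank (missing); ``sex`` accepts 0/1 or M/F coding.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"clinical table not found: {path}")
    df = pd.read_csv(path, sep="\t", dtype={"sample": str, "cancer_type": str})
    missing = [c for c in CLINICAL_COLUMNS[:7] if c not in df.columns]
    if missing:
        raise ValidationError(f"clinical table {path}: missing column(s) {missing}")
    records = []
    for row in df.itertuples(index=False):
        sex = row.sex
        if isinstance(sex, str):
            sex = {"M": 1, "F": 0, "male": 1, "female": 0}.get(sex, None)
            if sex is None:
                raise ValidationError(f"clinical table {path}: unparseable sex coding")
        stage = getattr(row, "stage", None)
        stage = None if stage is None or (isinstance(stage, float) and math.isnan(stage)) else int(stage)
        records.append(
            ClinicalRecord(
                sample_id=str(row.sample),
                time=float(row.time),
                event=int(row.event),
                age=float(row.age),
                sex=int(sex),
                tmb=float(row.tmb),
                stage=stage,
                cancer_type=str(getattr(row, "cancer_type", "")),
            )
        )
    return records


def write_clinical_table(records: Sequence[ClinicalRecord], path: str | Path) -> None:
    rows = [
        {
            "sample": r.sample_id,
            "time": repr(r.time),
            "event": r.event,
            "age": repr(r.age),
            "sex": r.sex,
            "tmb": repr(r.tmb),
            "stage": "" if r.stage is None else r.stage,
            "cancer_type": r.cancer_type,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=list(CLINICAL_COLUMNS)).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Effects table
# ---------------------------------------------------------------------------

EFFECT_COLUMNS = (
    "sample", "gene", "accession", "position", "ref", "alt", "cancer_type",
    "wt_avg", "mut_avg", "delta", "n_windows",
    "affect_label", "aberrant_label", "region_change", "on_ps_region",
)


def write_effects_table(effects: Sequence, path: str | Path) -> None:
    """Write one row per :class:`~psdelta.mutation_effect.MutationEffect`.

    Floats are serialized with ``repr`` (shortest round-trip decimal), so
    ``read_effects_table`` recovers them bit-exactly.
    """
    rows = []
    for e in effects:
        m = e.mutation
        rows.append(
            {
                "sample": m.sample_id,
                "gene": m.gene,
                "accession": m.accession,
                "position": m.position,
                "ref": m.ref_aa,
                "alt": m.alt_aa,
                "cancer_type": m.cancer_type,
                "wt_avg": repr(e.wt_avg),
                "mut_avg": repr(e.mut_avg),
                "delta": repr(e.delta),
                "n_windows": e.n_windows,
                "affect_label": e.affect_label,
                "aberrant_label": e.aberrant_label,
                "region_change": e.region_change,
                "on_ps_region": int(e.on_ps_region),
            }
        )
    try:
        pd.DataFrame(rows, columns=list(EFFECT_COLUMNS)).to_csv(path, sep="\t", index=False)
    except OSError as exc:
        raise InputError(f"cannot write effects table {path}: {exc}") from exc


def read_effects_table(path: str | Path) -> list:
    """Read an effects TSV written by :func:`write_effects_table`."""
    from .mutation_effect import MutationEffect  # local import: avoid cycle

    path = Path(path)
    if not path.exists():
        raise InputError(f"effects table not found: {path}")
    df = pd.read_csv(path, sep="\t", dtype={"sample": str, "gene": str, "accession": str}, float_precision="round_trip")
    missing = [c for c in EFFECT_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"effects table {path}: missing column(s) {missing}")
    effects = []
    for row in df.itertuples(index=False):
        mutation = MissenseMutation(
            sample_id=str(row.sample),
            gene=str(row.gene),
            accession=str(row.accession),
            position=int(row.position),
            ref_aa=str(row.ref),
            alt_aa=str(row.alt),
            cancer_type=str(row.cancer_type),
        )
        effects.append(
            MutationEffect(
                mutation=mutation,
                wt_avg=float(row.wt_avg),
                mut_avg=float(row.mut_avg),
                delta=float(row.delta),
                n_windows=int(row.n_windows),
                affect_label=str(row.affect_label),
                aberrant_label=str(row.aberrant_label),
                region_change=str(row.region_change),
                on_ps_region=bool(row.on_ps_region),
            )
        )
    return effects
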