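"""Readers and writers for the pipeline's standard formats.

Three lightweight containers move through the pipeline:

* :class:`AlignedSequenceSet` — a fixed-width nucleotide alignment keyed by
  sample id (aligned FASTA on disk);
* :class:`SampleTable` — sample metadata (id, sampling area, region, sex)
  as a tab-separated table;
* :class:`HaplotypeCatalog` — named haplotype profiles over a shared list of
  1-based polymorphic alignment columns, the compact representation used for
  every downstream statistic (a full-sequence alignment is never required).

Profile tables use the conventional dotted layout: the first haplotype row is
written explicitly and later rows show "." wherever they agree with it.  Both
"." and the typographic bullet "•" are accepted as the same-as-reference
marker; "-" is a real gap state.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

ALIGNMENT_ALPHABET = frozenset("ACGT-N")
CATALOG_ALPHABET = frozenset("ACGT-")
DOT_MARKERS = {".", "•"}  # "." and "•"

#: Sampling areas and the regional grouping used for the two-region analyses.
AREA_TO_REGION: Mapping[str, str] = {
    "LV": "eastern",
    "CO": "eastern",
    "ZA": "eastern",
    "KF": "western",
    "SI": "western",
}

SEX_CODES = frozenset("FMU")
_SEX_ALIASES = {
    "F": "F", "FEMALE": "F",
    "M": "M", "MALE": "M",
    "U": "U", "UNKNOWN": "U", "?": "U", "": "U", "NA": "U",
}


class AlignmentError(ValueError):
    """Raised for malformed alignments (ragged widths, illegal residues)."""


class MetadataError(ValueError):
    """Raised for malformed sample-metadata tables."""


class CatalogError(ValueError):
    """Raised for malformed haplotype-profile tables."""


@dataclass(frozen=True)
class AlignedSequenceSet:
    """A fixed-width alignment: every sequence spans ``n_columns`` columns.

    Columns are addressed 1-based throughout the package, matching the
    coordinate convention of printed polymorphic-site tables.
    """

    ids: tuple[str, ...]
    sequences: Mapping[str, str]
    n_columns: int

    def __post_init__(self) -> None:
        if self.n_columns < 1:
            raise AlignmentError("alignment must have at least one column")
        if len(set(self.ids)) != len(self.ids):
            dupes = sorted({i for i in self.ids if list(self.ids).count(i) > 1})
            raise AlignmentError(f"duplicate sequence ids: {dupes}")
        for sid in self.ids:
            seq = self.sequences[sid]
            if len(seq) != self.n_columns:
                raise AlignmentError(
                    f"record {sid!r} has width {len(seq)}, expected {self.n_columns}"
                )
            for col, ch in enumerate(seq, start=1):
                if ch not in ALIGNMENT_ALPHABET:
                    raise AlignmentError(
                        f"record {sid!r}: illegal residue {ch!r} at column {col}"
                    )

    def __len__(self) -> int:
        return len(self.ids)

    def __getitem__(self, sample_id: str) -> str:
        return self.sequences[sample_id]

    def states_at(self, sample_id: str, positions: Sequence[int]) -> str:
        """States of one sample at 1-based columns ``positions``."""
        seq = self.sequences[sample_id]
        return "".join(seq[p - 1] for p in positions)

    @classmethod
    def from_records(cls, records: Iterable[tuple[str, str]]) -> "AlignedSequenceSet":
        ids, seqs = [], {}
        width = None
        for sid, seq in records:
            seq = seq.upper()
            if width is None:
                width = len(seq)
            ids.append(sid)
            seqs[sid] = seq
        if width is None:
            raise AlignmentError("no sequence records")
        return cls(ids=tuple(ids), sequences=seqs, n_columns=width)


@dataclass(frozen=True)
class SampleTable:
    """Per-sample metadata: area code, region and sex."""

    frame: pd.DataFrame  # columns: sample_id, area, region, sex

    def __post_init__(self) -> None:
        df = self.frame
        required = {"sample_id", "area", "region", "sex"}
        missing = required - set(df.columns)
        if missing:
            raise MetadataError(f"missing metadata columns: {sorted(missing)}")
        if df["sample_id"].duplicated().any():
            dupes = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
            raise MetadataError(f"duplicate sample ids: {dupes}")
        bad_area = set(df["area"]) - set(AREA_TO_REGION)
        if bad_area:
            raise MetadataError(f"unknown area codes: {sorted(bad_area)}")
        for _, row in df.iterrows():
            if row["region"] != AREA_TO_REGION[row["area"]]:
                raise MetadataError(
                    f"sample {row['sample_id']!r}: region {row['region']!r} "
                    f"inconsistent with area {row['area']!r}"
                )
        bad_sex = set(df["sex"]) - SEX_CODES
        if bad_sex:
            raise MetadataError(f"sex codes outside {{F,M,U}}: {sorted(bad_sex)}")

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def sample_ids(self) -> list[str]:
        return self.frame["sample_id"].tolist()

    def group_of(self, group_by: str) -> dict[str, str]:
        """Map sample_id -> grouping label (``area`` or ``region``)."""
        if group_by not in ("area", "region"):
            raise MetadataError(f"group_by must be 'area' or 'region', got {group_by!r}")
        return dict(zip(self.frame["sample_id"], self.frame[group_by]))


@dataclass(frozen=True)
class HaplotypeCatalog:
    """Named haplotype profiles over shared 1-based polymorphic columns.

    ``states[name]`` holds one explicit symbol per position; the dotted
    shorthand of profile tables is expanded on read.
    """

    positions: tuple[int, ...]
    names: tuple[str, ...]
    states: Mapping[str, str]

    def __post_init__(self) -> None:
        pos = self.positions
        if any(b <= a for a, b in zip(pos, pos[1:])):
            raise CatalogError("positions must be strictly increasing")
        if pos and pos[0] < 1:
            raise CatalogError("positions are 1-based; found a value < 1")
        if len(set(self.names)) != len(self.names):
            raise CatalogError("haplotype names must be unique")
        seen: dict[str, str] = {}
        for name in self.names:
            vec = self.states[name]
            if len(vec) != len(pos):
                raise CatalogError(
                    f"haplotype {name!r} has {len(vec)} states for {len(pos)} positions"
                )
            bad = set(vec) - CATALOG_ALPHABET
            if bad:
                raise CatalogError(f"haplotype {name!r}: illegal state(s) {sorted(bad)}")
            if vec in seen:
                raise CatalogError(
                    f"haplotypes {seen[vec]!r} and {name!r} share an identical profile"
                )
            seen[vec] = name

    def __len__(self) -> int:
        return len(self.names)

    def profile(self, name: str) -> str:
        return self.states[name]

    def subset(self, names: Sequence[str]) -> "HaplotypeCatalog":
        missing = set(names) - set(self.names)
        if missing:
            raise CatalogError(f"unknown haplotypes: {sorted(missing)}")
        return HaplotypeCatalog(
            positions=self.positions,
            names=tuple(names),
            states={n: self.states[n] for n in names},
        )

    def with_added(self, name: str, states: str) -> "HaplotypeCatalog":
        return HaplotypeCatalog(
            positions=self.positions,
            names=self.names + (name,),
            states={**dict(self.states), name: states},
        )


# ---------------------------------------------------------------------------
# FASTA

def read_alignment(path: str | os.PathLike) -> AlignedSequenceSet:
    """Read an aligned multi-FASTA; residues are upper-cased and validated."""
    records = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise AlignmentError(f"no FASTA records in {path}")
    width = len(records[0][1])
    for sid, seq in records:
        if len(seq) != width:
            raise AlignmentError(
                f"ragged alignment: record {sid!r} has width {len(seq)}, "
                f"first record has {width}"
            )
    return AlignedSequenceSet.from_records(records)


def write_alignment(aln: AlignedSequenceSet, path: str | os.PathLike) -> None:
    recs = [
        SeqRecord(Seq(aln.sequences[sid]), id=sid, description="")
        for sid in aln.ids
    ]
    SeqIO.write(recs, str(path), "fasta")


# ---------------------------------------------------------------------------
# Sample metadata

def read_sample_metadata(path: str | os.PathLike) -> SampleTable:
    """Read a TSV with columns sample_id, area[, region][, sex].

    Region is derived from the area when absent; sex strings are normalised
    to {F, M, U} (missing sex becomes U).
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    if "sample_id" not in df.columns or "area" not in df.columns:
        raise MetadataError("metadata requires 'sample_id' and 'area' columns")
    df["area"] = df["area"].str.strip().str.upper()
    bad_area = set(df["area"]) - set(AREA_TO_REGION)
    if bad_area:
        raise MetadataError(f"unknown area codes: {sorted(bad_area)}")
    if "region" not in df.columns or (df.get("region", "") == "").all():
        df["region"] = df["area"].map(AREA_TO_REGION)
    else:
        df["region"] = [
            AREA_TO_REGION[a] if r == "" else r.strip().lower()
            for a, r in zip(df["area"], df["region"])
        ]
    if "sex" not in df.columns:
        df["sex"] = "U"
    sexes = []
    for s in df["sex"]:
        key = s.strip().upper()
        if key not in _SEX_ALIASES:
            raise MetadataError(f"unrecognised sex value {s!r}")
        sexes.append(_SEX_ALIASES[key])
    df["sex"] = sexes
    return SampleTable(frame=df[["sample_id", "area", "region", "sex"]].copy())


def write_sample_metadata(table: SampleTable, path: str | os.PathLike) -> None:
    table.frame.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Haplotype-profile tables

def read_profile_table(path: str | os.PathLike) -> HaplotypeCatalog:
    """Read a dotted profile table (positions across, haplotypes down)."""
    with open(path, encoding="utf-8") as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if len(lines) < 2:
        raise CatalogError("profile table needs a header and at least one haplotype")
    header = lines[0].split("\t")
    try:
        positions = tuple(int(p) for p in header[1:])
    except ValueError as exc:
        raise CatalogError(f"non-integer position in header: {exc}") from None
    if any(b <= a for a, b in zip(positions, positions[1:])):
        raise CatalogError("position columns must be strictly increasing")
    names: list[str] = []
    states: dict[str, str] = {}
    reference: str | None = None
    for ln in lines[1:]:
        cells = ln.split("\t")
        name, symbols = cells[0], cells[1:]
        if len(symbols) != len(positions):
            raise CatalogError(
                f"haplotype {name!r}: {len(symbols)} states for {len(positions)} positions"
            )
        expanded = []
        for i, sym in enumerate(symbols):
            sym = sym.strip()
            if sym in DOT_MARKERS:
                if reference is None:
                    raise CatalogError(
                        f"haplotype {name!r}: dot in the reference (first) row"
                    )
                expanded.append(reference[i])
            else:
                sym = sym.upper()
                if sym not in CATALOG_ALPHABET:
                    raise CatalogError(
                        f"haplotype {name!r}: illegal state {sym!r} "
                        f"at position {positions[i]}"
                    )
                expanded.append(sym)
        vec = "".join(expanded)
        if reference is None:
            reference = vec
        names.append(name)
        states[name] = vec
    return HaplotypeCatalog(positions=positions, names=tuple(names), states=states)


def write_profile_table(catalog: HaplotypeCatalog, path: str | os.PathLike) -> None:
    """Write a profile table, re-compressing against the first haplotype."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("haplotype\t" + "\t".join(str(p) for p in catalog.positions) + "\n")
        reference: str | None = None
        for name in catalog.names:
            vec = catalog.states[name]
            if reference is None:
                reference = vec
                cells = list(vec)
            else:
                cells = [s if s != r else "." for s, r in zip(vec, reference)]
            fh.write(name + "\t" + "\t".join(cells) + "\n")
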