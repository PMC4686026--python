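"""Polymorphic-site detection, substitution classification and haplotype calling.

A column is polymorphic when at least two distinct non-N states occur in it.
Each polymorphic column receives exactly one class:

* indel — a gap ("-") occurs in the column (gap columns are counted
  per column, so a two-column deletion contributes two indels);
* transversion — some pair of observed bases crosses the purine/pyrimidine
  divide;
* transition — otherwise (all base pairs are purine–purine or
  pyrimidine–pyrimidine).

Haplotype calling matches each sample's states at the catalog's diagnostic
columns against the cataloged profiles.  Samples matching no profile are
grouped by their state vector and minted as new haplotypes; a newly minted
haplotype observed only once is flagged ``needs_verification`` — the survey
convention that singletons must be confirmed by re-sequencing before being
accepted as real.  "N" never matches a state: a sample carrying N at any
diagnostic column cannot be called and is reported as unresolvable.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

from .io import AlignedSequenceSet, HaplotypeCatalog

PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")


class HaplotypingError(ValueError):
    """Raised on contract violations during site detection or calling."""


class UnresolvableCallError(HaplotypingError):
    """Samples with N at a diagnostic column cannot be assigned a haplotype."""

    def __init__(self, sample_ids: Sequence[str]):
        self.sample_ids = list(sample_ids)
        super().__init__(
            "samples with N at diagnostic positions (drop or re-sequence): "
            + ", ".join(self.sample_ids)
        )


@dataclass(frozen=True)
class PolymorphismSummary:
    """Counts of polymorphic columns by substitution class."""

    n_sites: int
    site_positions: tuple[int, ...]
    n_transitions: int | None = None
    n_transversions: int | None = None
    n_indels: int | None = None

    def __post_init__(self) -> None:
        if list(self.site_positions) != sorted(set(self.site_positions)):
            raise HaplotypingError("site_positions must be sorted and unique")
        if self.n_sites != len(self.site_positions):
            raise HaplotypingError("n_sites inconsistent with site_positions")
        classes = (self.n_transitions, self.n_transversions, self.n_indels)
        if all(c is not None for c in classes) and sum(classes) != self.n_sites:
            raise HaplotypingError(
                "transition + transversion + indel counts must equal n_sites"
            )


@dataclass(frozen=True)
class HaplotypeAssignment:
    sample_id: str
    haplotype: str
    is_novel: bool = False
    needs_verification: bool = False

    def __post_init__(self) -> None:
        if self.needs_verification and not self.is_novel:
            raise HaplotypingError("needs_verification implies is_novel")


def _column_states(source: AlignedSequenceSet | HaplotypeCatalog):
    """Yield (1-based position, list of per-row states) for every column."""
    if isinstance(source, HaplotypeCatalog):
        for i, pos in enumerate(source.positions):
            yield pos, [source.states[n][i] for n in source.names]
    else:
        for i in range(source.n_columns):
            yield i + 1, [source.sequences[s][i] for s in source.ids]


def _n_rows(source: AlignedSequenceSet | HaplotypeCatalog) -> int:
    return len(source.names) if isinstance(source, HaplotypeCatalog) else len(source.ids)


def find_polymorphic_sites(
    source: AlignedSequenceSet | HaplotypeCatalog,
) -> PolymorphismSummary:
    """Locate columns with two or more distinct non-N states.

    Substitution classes are left unfilled; use
    :func:`classify_polymorphisms` or :func:`summarize_polymorphisms`.
    """
    if _n_rows(source) < 2:
        raise HaplotypingError("polymorphism is undefined for fewer than 2 sequences")
    positions = []
    for pos, states in _column_states(source):
        observed = set(states) - {"N"}
        if len(observed) >= 2:
            positions.append(pos)
    return PolymorphismSummary(n_sites=len(positions), site_positions=tuple(positions))


def classify_column(states: Sequence[str]) -> str:
    """Class of one polymorphic column: 'indel', 'transition' or 'transversion'."""
    observed = set(states) - {"N"}
    if len(observed) < 2:
        raise HaplotypingError("column is not polymorphic")
    if "-" in observed:
        return "indel"
    for a in observed:
        for b in observed:
            if (a in PURINES) != (b in PURINES):
                return "transversion"
    return "transition"


def classify_polymorphisms(
    summary: PolymorphismSummary,
    states_per_column: Mapping[int, Sequence[str]],
) -> PolymorphismSummary:
    """Fill the class counts of ``summary`` from per-column state lists."""
    tallies = {"transition": 0, "transversion": 0, "indel": 0}
    for pos in summary.site_positions:
        tallies[classify_column(states_per_column[pos])] += 1
    return replace(
        summary,
        n_transitions=tallies["transition"],
        n_transversions=tallies["transversion"],
        n_indels=tallies["indel"],
    )


def summarize_polymorphisms(
    source: AlignedSequenceSet | HaplotypeCatalog,
) -> PolymorphismSummary:
    """Detect polymorphic columns and classify them in one pass."""
    summary = find_polymorphic_sites(source)
    states = {pos: st for pos, st in _column_states(source)}
    return classify_polymorphisms(summary, states)


def _next_novel_index(names: Sequence[str], prefix: str) -> int:
    pattern = re.compile(rf"^{re.escape(prefix)}(\d+)$")
    best = 0
    for name in names:
        m = pattern.match(name)
        if m:
            best = max(best, int(m.group(1)))
    return best + 1


def call_haplotypes(
    aln: AlignedSequenceSet,
    catalog: HaplotypeCatalog,
    novel_prefix: str = "Z",
) -> tuple[list[HaplotypeAssignment], HaplotypeCatalog]:
    """Assign every sample a haplotype name; mint novel haplotypes as needed.

    Returns the assignments (in alignment order) and a catalog extended with
    any newly minted profiles.  Novel names continue the highest existing
    index under ``novel_prefix`` and are assigned in first-seen order.
    """
    if len(aln) == 0:
        raise HaplotypingError("empty alignment")
    if catalog.positions and aln.n_columns < max(catalog.positions):
        raise HaplotypingError(
            f"alignment width {aln.n_columns} does not cover catalog position "
            f"{max(catalog.positions)}"
        )
    profile_to_name = {catalog.states[n]: n for n in catalog.names}

    ambiguous = [
        sid for sid in aln.ids
        if "N" in aln.states_at(sid, catalog.positions)
    ]
    if ambiguous:
        raise UnresolvableCallError(ambiguous)

    names: dict[str, str] = {}
    novel_members: dict[str, list[str]] = {}  # vector -> sample ids
    novel_order: list[str] = []
    for sid in aln.ids:
        vec = aln.states_at(sid, catalog.positions)
        if vec in profile_to_name:
            names[sid] = profile_to_name[vec]
        else:
            if vec not in novel_members:
                novel_members[vec] = []
                novel_order.append(vec)
            novel_members[vec].append(sid)

    updated = catalog
    next_idx = _next_novel_index(catalog.names, novel_prefix)
    vec_to_new_name: dict[str, str] = {}
    for vec in novel_order:
        name = f"{novel_prefix}{next_idx}"
        next_idx += 1
        vec_to_new_name[vec] = name
        updated = updated.with_added(name, vec)

    assignments = []
    for sid in aln.ids:
        vec = aln.states_at(sid, catalog.positions)
        if vec in vec_to_new_name:
            assignments.append(
                HaplotypeAssignment(
                    sample_id=sid,
                    haplotype=vec_to_new_name[vec],
                    is_novel=True,
                    needs_verification=len(novel_members[vec]) == 1,
                )
            )
        else:
            assignments.append(HaplotypeAssignment(sample_id=sid, haplotype=names[sid]))
    return assignments, updated


def profile_to_sequence(
    catalog: HaplotypeCatalog, name: str, background: str
) -> str:
    """Write a haplotype's states into a background sequence.

    The inverse of calling: ``call_haplotypes`` on the result recovers
    ``name`` (given a background wide enough to cover every catalog column).
    """
    if name not in catalog.states:
        raise HaplotypingError(f"unknown haplotype {name!r}")
    if catalog.positions and len(background) < max(catalog.positions):
        raise HaplotypingError(
            f"background width {len(background)} < max catalog position "
            f"{max(catalog.positions)}"
        )
    seq = list(background)
    for pos, state in zip(catalog.positions, catalog.states[name]):
        seq[pos - 1] = state
    return "".join(seq)
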