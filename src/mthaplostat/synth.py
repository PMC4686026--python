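"""Study-shaped synthetic data.

The generator reproduces the structure of the Zambian lion mtDNA survey
without requiring any sequence download: each simulated individual carries
one of the cataloged 12S–16S haplotypes, embedded at the cataloged
polymorphic columns into a random background sequence whose base
composition matches the survey's published nucleotide composition.  The
default design reproduces the survey's sampling table cell for cell —
165 individuals over five areas (LV, CO, ZA, KF, SI), eight haplotypes,
119 males / 45 females / 1 unknown.

All statistics downstream of haplotype calling depend only on haplotype
identities and counts, which the generator fixes exactly; a single shared
background per run is therefore used (invariant columns cancel everywhere
except in the per-site denominator of nucleotide diversity).  Optional
noise replaces background positions with "N" at a given per-site rate;
diagnostic (catalog) columns are left noise-free unless explicitly
requested, so that calling remains exact under background noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .io import (
    AREA_TO_REGION,
    AlignedSequenceSet,
    HaplotypeCatalog,
    SampleTable,
)
from .haplotyping import profile_to_sequence

AREAS = ("LV", "CO", "ZA", "KF", "SI")
SEXES = ("F", "M", "U")

#: Background base composition: the survey's published nucleotide
#: composition for the Zambian haplotypes (fractions of C, T, A, G).
DEFAULT_COMPOSITION: Mapping[str, float] = {
    "C": 0.2211,
    "T": 0.2267,
    "A": 0.3664,
    "G": 0.1858,
}

DEFAULT_WIDTH = 1882


class DesignError(ValueError):
    pass


@dataclass(frozen=True)
class StudyDesign:
    """Sampling design: how many individuals of each haplotype, area and sex."""

    counts: Mapping[tuple[str, str, str], int]  # (area, haplotype, sex) -> n
    width: int = DEFAULT_WIDTH
    composition: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COMPOSITION)
    )
    noise_rate: float = 0.0
    noise_diagnostic: bool = False

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.counts.values()):
            raise DesignError("negative design counts")
        if abs(sum(self.composition.values()) - 1.0) > 1e-9:
            raise DesignError("background composition must sum to 1")
        if not 0.0 <= self.noise_rate <= 1.0:
            raise DesignError("noise rate must lie in [0, 1]")
        for area, _hap, sex in self.counts:
            if area not in AREA_TO_REGION:
                raise DesignError(f"unknown area {area!r}")
            if sex not in SEXES:
                raise DesignError(f"unknown sex code {sex!r}")

    @property
    def n_samples(self) -> int:
        return sum(self.counts.values())

    @property
    def haplotypes(self) -> tuple[str, ...]:
        seen = []
        for _area, hap, _sex in self.counts:
            if hap not in seen:
                seen.append(hap)
        return tuple(seen)

    def scaled(self, factor: int) -> "StudyDesign":
        return StudyDesign(
            counts={k: v * factor for k, v in self.counts.items()},
            width=self.width,
            composition=self.composition,
            noise_rate=self.noise_rate,
            noise_diagnostic=self.noise_diagnostic,
        )


def design_from_table(path) -> StudyDesign:
    """Read a design TSV: haplotype rows, AREA_SEX count columns."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.empty or "haplotype" not in df.columns:
        raise DesignError("design table needs a 'haplotype' column and rows")
    counts: dict[tuple[str, str, str], int] = {}
    for col in df.columns:
        if col == "haplotype":
            continue
        try:
            area, sex = col.rsplit("_", 1)
        except ValueError:
            raise DesignError(f"malformed design column {col!r}") from None
        for hap, raw in zip(df["haplotype"], df[col]):
            value = int(raw)
            if value:
                counts[(area, hap, sex)] = value
    if not counts:
        raise DesignError("design table contains no samples")
    return StudyDesign(counts=counts)


def generate_study(
    design: StudyDesign,
    catalog: HaplotypeCatalog | None = None,
    seed: int = 0,
) -> tuple[AlignedSequenceSet, SampleTable, HaplotypeCatalog]:
    """Simulate an aligned FASTA + metadata table under the design.

    Fully reproducible from ``seed``.  Sample order is fixed: areas in the
    survey's column order, haplotypes in catalog order, sexes F, M, U.
    """
    if catalog is None:
        from .datasets import load_reference_catalog

        catalog = load_reference_catalog()
    unknown = {h for _a, h, _s in design.counts} - set(catalog.names)
    if unknown:
        raise DesignError(f"haplotypes not in catalog: {sorted(unknown)}")
    if catalog.positions and design.width < max(catalog.positions):
        raise DesignError(
            f"width {design.width} < max catalog position {max(catalog.positions)}"
        )

    rng = np.random.default_rng(seed)
    bases = list(design.composition)
    probs = np.array([design.composition[b] for b in bases])
    background = "".join(rng.choice(bases, size=design.width, p=probs))
    diagnostic = np.zeros(design.width, dtype=bool)
    for pos in catalog.positions:
        diagnostic[pos - 1] = True

    ids: list[str] = []
    seqs: dict[str, str] = {}
    meta_rows = []
    serial = 0
    hap_order = [h for h in catalog.names if h in design.haplotypes]
    for area in AREAS:
        for hap in hap_order:
            for sex in SEXES:
                for _ in range(design.counts.get((area, hap, sex), 0)):
                    serial += 1
                    sid = f"ZL{serial:03d}"
                    seq = profile_to_sequence(catalog, hap, background)
                    if design.noise_rate > 0:
                        mask = rng.random(design.width) < design.noise_rate
                        if not design.noise_diagnostic:
                            mask &= ~diagnostic
                        if mask.any():
                            arr = np.array(list(seq))
                            arr[mask] = "N"
                            seq = "".join(arr)
                    ids.append(sid)
                    seqs[sid] = seq
                    meta_rows.append(
                        {
                            "sample_id": sid,
                            "area": area,
                            "region": AREA_TO_REGION[area],
                            "sex": sex,
                        }
                    )
    aln = AlignedSequenceSet(ids=tuple(ids), sequences=seqs, n_columns=design.width)
    table = SampleTable(frame=pd.DataFrame(meta_rows))
    return aln, table, catalog
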