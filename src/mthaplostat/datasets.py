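"""Packaged reference data.

* ``load_reference_catalog()`` — the 17 published 12S–16S lion haplotype
  profiles (H1–H12 range-wide, Z1–Z5 from Zambia) over 31 polymorphic
  alignment columns.
* ``load_default_design()`` — the Zambian sampling design: per-area,
  per-haplotype, per-sex sample counts for the 165 surveyed individuals.
"""

from __future__ import annotations

from importlib import resources

from .io import HaplotypeCatalog, read_profile_table

#: The eight haplotypes observed in the Zambian survey.
ZAMBIAN_HAPLOTYPES = ("H1", "H9", "H11", "Z1", "Z2", "Z3", "Z4", "Z5")


def _data_path(name: str):
    return resources.files("mthaplostat.data").joinpath(name)


def load_reference_catalog() -> HaplotypeCatalog:
    with resources.as_file(_data_path("haplotype_profiles.tsv")) as p:
        return read_profile_table(p)


def load_zambian_catalog() -> HaplotypeCatalog:
    """The reference catalog restricted to haplotypes found in Zambia."""
    return load_reference_catalog().subset(ZAMBIAN_HAPLOTYPES)


def load_default_design():
    from .synth import design_from_table

    with resources.as_file(_data_path("study_design.tsv")) as p:
        return design_from_table(p)
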