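"""Shared fixtures: packaged catalog, default design, one synthetic survey."""

from collections import Counter

import pytest

import mthaplostat as mh


@pytest.fixture(scope="session")
def reference_catalog():
    return mh.load_reference_catalog()


@pytest.fixture(scope="session")
def zambian_catalog():
    return mh.load_zambian_catalog()


@pytest.fixture(scope="session")
def default_design():
    return mh.load_default_design()


@pytest.fixture(scope="session")
def study(default_design):
    """One noise-free synthetic survey (165 samples), seed 1."""
    return mh.generate_study(default_design, seed=1)


@pytest.fixture(scope="session")
def study_calls(study, reference_catalog):
    aln, meta, _catalog = study
    assignments, updated = mh.call_haplotypes(aln, reference_catalog)
    return assignments, updated, meta


@pytest.fixture(scope="session")
def study_counts(study_calls):
    """Haplotype counts of the synthetic survey, overall and per pool."""
    assignments, _updated, meta = study_calls
    hap_of = {a.sample_id: a.haplotype for a in assignments}
    area_of = meta.group_of("area")
    region_of = meta.group_of("region")
    overall = Counter(hap_of.values())
    by_area = {}
    by_region = {}
    for sid in meta.sample_ids:
        by_area.setdefault(area_of[sid], Counter())[hap_of[sid]] += 1
        by_region.setdefault(region_of[sid], Counter())[hap_of[sid]] += 1
    return {"overall": overall, "area": by_area, "region": by_region}
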