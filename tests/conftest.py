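"""Shared fixtures: small record builders and a noise-free cohort on disk."""

from __future__ import annotations

import pytest

from provlink.config import RunConfig
from provlink.records_io import (
    LicensureRecord,
    NPPESRecord,
    PostalAddress,
    ProviderName,
    TaxonomyCode,
)
from provlink.synthetic_data import ErrorConfig, generate_cohort


def make_licensure(
    first="Helen",
    last="Black",
    street="1705 Park Ave",
    city="Hartford",
    state="CT",
    license_number="001122",
    provider_type="certified_nurse_midwife",
    year=2017,
    **name_kw,
):
    return LicensureRecord(
        license_number=license_number,
        provider_type=provider_type,
        name=ProviderName(first=first, last=last, **name_kw),
        address=PostalAddress(street=street, city=city, state=state, zip="06101"),
        year=year,
    )


def make_nppes(
    first="Helen",
    last="Black",
    street="1705 Park Avenue",
    city="Hartford",
    state="CT",
    npi="1234567893",
    tax1="367A00000X",
    tax2=None,
    year=2017,
    gender="F",
    phone="8605550100",
    mailing=None,
    **name_kw,
):
    practice = PostalAddress(street=street, city=city, state=state, zip="06101")
    return NPPESRecord(
        npi=npi,
        name=ProviderName(first=first, last=last, **name_kw),
        gender=gender,
        phone=phone,
        taxonomy_primary=TaxonomyCode(tax1),
        taxonomy_secondary=TaxonomyCode(tax2) if tax2 else None,
        mailing_address=mailing or practice,
        practice_address=practice,
        other_identifiers=(),
        year=year,
    )


@pytest.fixture(scope="session")
def default_config():
    return RunConfig()


@pytest.fixture(scope="session")
def clean_cohort_dir(tmp_path_factory):
    """A 120-identity noise-free cohort written to disk (session-shared)."""
    out = tmp_path_factory.mktemp("clean_cohort")
    cohort = generate_cohort(120, seed=42, errors=ErrorConfig(), out_dir=out)
    return cohort


@pytest.fixture()
def nppes_paths(clean_cohort_dir):
    return {
        year: clean_cohort_dir.paths[f"nppes_{year}"]
        for year in range(2013, 2018)
    }
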