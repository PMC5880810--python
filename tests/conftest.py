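"""Shared fixtures: shipped configs, group fixtures, cached extractions."""

from __future__ import annotations

import pytest

from aquasig.extraction import extract_for_query
from aquasig.refdata import load_shipped_annotations, load_shipped_rules
from aquasig.synth import GROUP_IDS, GROUP_TEMPLATES, make_group_fixtures


@pytest.fixture(scope="session")
def annotations():
    return load_shipped_annotations()


@pytest.fixture(scope="session")
def rulesets(annotations):
    return load_shipped_rules()


@pytest.fixture(scope="session")
def group_fixtures():
    """One synthetic sequence per expression group, keyed by group id."""
    return dict(zip(GROUP_IDS, make_group_fixtures(seed=1)))


@pytest.fixture(scope="session")
def extractions(annotations, group_fixtures):
    """Alignment-anchored residue extraction per group fixture."""
    out = {}
    for gid, rec in group_fixtures.items():
        cls = GROUP_TEMPLATES[gid].class_label
        out[gid] = extract_for_query(rec, annotations[cls])
    return out
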