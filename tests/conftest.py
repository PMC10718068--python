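"""Shared fixtures: the toy bundle and one full pipeline run per session."""

from __future__ import annotations

import pytest

from biocatmap.fixtures import make_fixture_bundle
from biocatmap.mapping import rule_edit_counts
from biocatmap.pipeline import run_pipeline
from biocatmap.records import ReactionRule

OXIDATION_SMARTS = "[C;!$(C=O):1][OX2H1:2].[O:3]=[O:4]>>[C:1]=[O:2].[OH:3][OH:4]"
HYDRATION_SMARTS = "[CH:1]#[CH:2].[OH2:3]>>[CH3:1][CH:2]=[O:3]"


def make_rule(rule_id: str, smarts: str, applicability: int = 0) -> ReactionRule:
    rule = ReactionRule(rule_id, smarts, *rule_edit_counts(smarts))
    rule.applicability_count = applicability
    return rule


@pytest.fixture(scope="session")
def bundle():
    return make_fixture_bundle(seed=0)


@pytest.fixture(scope="session")
def pipeline_output(bundle):
    return run_pipeline(bundle.entries, bundle.ligands, bundle.rules)


@pytest.fixture(scope="session")
def records(pipeline_output):
    return pipeline_output[0]


@pytest.fixture(scope="session")
def report(pipeline_output):
    return pipeline_output[1]


@pytest.fixture()
def oxidation_rule():
    return make_rule("R02_alcohol_oxidase", OXIDATION_SMARTS)


@pytest.fixture()
def hydration_rule():
    return make_rule("R01_alkyne_hydration", HYDRATION_SMARTS)
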