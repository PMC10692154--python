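from __future__ import annotations

import pytest

from complexkit import FixtureConfig, generate_archive, reference_examples
from complexkit.identity import IdentifierRegistry, eligibility, group_unique, mark_preferred


def identify(assemblies, registry=None):
    """Run the identification stage: preferred -> eligible -> unique groups."""
    preferred = mark_preferred(assemblies)
    eligible = [a for a in preferred if eligibility(a)[0]]
    return group_unique(eligible, registry or IdentifierRegistry())


def truth_by_md5(bundle, uniques):
    """Map each unique group's md5 to its single intended truth record."""
    out = {}
    for u in uniques:
        gids = {bundle.truth.assembly_group[m] for m in u.members}
        assert len(gids) == 1, f"group mixes truth ids: {gids}"
        out[u.md5_hex] = bundle.truth.groups[gids.pop()]
    return out


@pytest.fixture(scope="session")
def ref_bundle():
    return reference_examples()


@pytest.fixture(scope="session")
def ref_uniques(ref_bundle):
    return identify(ref_bundle.assemblies)


@pytest.fixture(scope="session")
def default_bundle():
    return generate_archive(FixtureConfig(seed=11))


@pytest.fixture(scope="session")
def default_uniques(default_bundle):
    return identify(default_bundle.assemblies)
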