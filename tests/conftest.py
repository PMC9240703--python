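import pytest

import relframe as rf

# The full published derivation table for the complex mixed network
# (base: gkuj, h<i, i<k, k<j, l<o, mkuk, n=o, p>o): 48 relation strings.
TUTORIAL3_RELATIONS = frozenset(
    [
        # trained and mutually entailed
        "gkuj", "h < i", "i > h", "i < k", "jkug", "j > k", "k > i", "k < j",
        "kkum", "l < o", "mkuk", "n = o", "o > l", "o = n", "o < p", "p > o",
        # combinatorially derived, determinate
        "h < k", "i < j", "j > i", "k > h",
        "l < n", "l < p", "n > l", "n < p", "p > l", "p > n",
        "h < j", "j > h",
        # combinatorially derived, known-unknown
        "hkui", "ikuh", "ikuk", "jkuk", "kkui", "kkuj",
        "hkuk", "ikuj", "jkui", "kkuh",
        "lkun", "lkuo", "nkul", "nkuo", "nkup",
        "okul", "okun", "okup", "pkun", "pkuo",
    ]
)

# The combinatorially derived known-unknown statements among the above.
TUTORIAL3_DERIVED_KU = frozenset(
    [
        "hkui", "ikuh", "ikuk", "jkuk", "kkui", "kkuj",
        "hkuk", "ikuj", "jkui", "kkuh",
        "lkun", "lkuo", "nkul", "nkuo", "nkup",
        "okul", "okun", "okup", "pkun", "pkuo",
    ]
)


@pytest.fixture(scope="session")
def table1():
    return rf.relation_train(rf.fixture("tutorial1"))


@pytest.fixture(scope="session")
def table2_off():
    return rf.relation_train(rf.fixture("tutorial2"), rf.KUMode.OFF)


@pytest.fixture(scope="session")
def table2_emit():
    return rf.relation_train(rf.fixture("tutorial2"), rf.KUMode.EMIT)


@pytest.fixture(scope="session")
def table3():
    return rf.relation_train(rf.fixture("tutorial3"), rf.KUMode.EMIT)


def relations(table):
    return {s.render() for s in table.statements()}
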