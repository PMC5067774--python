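"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from isotail import MatureArm, MirnaReference, demo_reference


# ---------------------------------------------------------------------------
# independent oracles (kept free of any isotail decomposition code)


def brute_force_decompose(
    read: str, template: str, arm_start: int, arm_end: int, offset5: int
) -> tuple[int, str]:
    """Enumerate every (templated prefix, tail) split and keep the longest
    feasible templated prefix — the reference answer for greedy 3'-end
    decomposition."""
    start = arm_start + offset5
    best = 0
    for tlen in range(len(read) + 1):
        if start + tlen <= len(template) and read[:tlen] == template[start : start + tlen]:
            best = tlen
    return (start + best) - arm_end, read[best:]


def pooled_t(a, b) -> tuple[float, float]:
    """Hand-computed pooled-variance two-sample t statistic and two-sided p."""
    from scipy.stats import t as tdist

    a = np.asarray(a, float)
    b = np.asarray(b, float)
    na, nb = len(a), len(b)
    df = na + nb - 2
    sp2 = (((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()) / df
    t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb))
    p = 2 * tdist.sf(abs(t), df)
    return float(t), float(p)


def random_toy_reference(rng: np.random.Generator, index: int) -> MirnaReference:
    """A random single-arm precursor with ample 3' template context."""
    n = int(rng.integers(60, 90))
    seq = "".join(rng.choice(list("ACGT"), size=n))
    arm_len = int(rng.integers(16, 26))
    start = int(rng.integers(3, n - arm_len - 12))
    return MirnaReference(
        f"toy-{index}", seq, (MatureArm(f"toy-{index}-5p", start, start + arm_len),)
    )


# ---------------------------------------------------------------------------
# fixtures


@pytest.fixture
def spec_ref() -> MirnaReference:
    """25-nt toy precursor with a 16-nt arm; context supplied explicitly
    because only 9 nt of precursor remain 3' of the arm."""
    return MirnaReference(
        "toy-T",
        "AAGGCCUUAAGGCCUUCGAUCGAUU",
        (MatureArm("miR-T-5p", 0, 16),),
        {"miR-T-5p": "CGATCGATTA"},
    )


@pytest.fixture
def demo_ref() -> MirnaReference:
    return demo_reference()


@pytest.fixture
def two_arm_ref() -> MirnaReference:
    """40-nt precursor with arms [0,16) and [20,36) (loop = [16,20))."""
    rng = np.random.default_rng(7)
    seq = "".join(rng.choice(list("ACGT"), size=40))
    return MirnaReference(
        "toy-2arm", seq,
        (MatureArm("toy-2arm-5p", 0, 16), MatureArm("toy-2arm-3p", 20, 36)),
        {"toy-2arm-3p": seq[36:] + "GATTAC"},
    )
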