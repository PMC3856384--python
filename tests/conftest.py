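"""Shared fixtures: the phantom regression suites are expensive, so they run
once per session and tests consume the recorded statistics."""

from __future__ import annotations

import time

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from wscalp import (
    HumanParams,
    MacaqueParams,
    extract_brain_human,
    extract_brain_macaque,
    human_phantom_spec,
    macaque_phantom_spec,
    make_phantom,
    overlap,
)

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

HUMAN_SEEDS = list(range(10))
MACAQUE_SEEDS = list(range(5))


def run_human_seed(seed: int, *, marrow: bool = False) -> dict:
    spec = human_phantom_spec(seed, marrow=marrow)
    vol, truth = make_phantom(spec)
    tb = truth["brain"]
    t0 = time.time()
    res = extract_brain_human(vol, HumanParams(), smooth=True)
    seconds = time.time() - t0
    s1 = overlap(res.stage1_mask, tb)
    s2 = overlap(res.stage2_mask, tb)
    s2s = overlap(res.stage2_smoothed, tb)
    ma = res.trace["M_A"].data
    nf = res.trace["N_F"].data
    return {
        "seed": seed,
        "marrow": marrow,
        "seconds": seconds,
        "stage1_sensitivity": s1.sensitivity,
        "stage1_dice": s1.dice,
        "stage2_dice": s2.dice,
        "stage2_sensitivity": s2.sensitivity,
        "stage2_smoothed_dice": s2s.dice,
        "fp_stage1": int((res.stage1_mask.data & ~tb.data).sum()),
        "fp_stage2": int((res.stage2_mask.data & ~tb.data).sum()),
        "ma_outside_truth": int((ma & ~tb.data).sum()),
        "nf_inside_truth": int((nf & tb.data).sum()),
    }


def run_macaque_seed(seed: int) -> dict:
    spec = macaque_phantom_spec(seed, bias_amp=0.5)
    vol, truth = make_phantom(spec)
    tb = truth["brain"]
    t0 = time.time()
    res = extract_brain_macaque(vol, MacaqueParams(), bias_correct=True)
    seconds = time.time() - t0
    s1 = overlap(res.stage1_mask, tb)
    s2 = overlap(res.stage2_mask, tb)
    return {
        "seed": seed,
        "seconds": seconds,
        "stage1_sensitivity": s1.sensitivity,
        "stage2_dice": s2.dice,
        "stage2_subset_stage1": bool(
            np.all(res.stage2_mask.data <= res.stage1_mask.data)
        ),
    }


@pytest.fixture(scope="session")
def human_suite():
    """10-seed default human phantom regression suite (scores only)."""
    return [run_human_seed(s) for s in HUMAN_SEEDS]


@pytest.fixture(scope="session")
def marrow_run():
    """Bright-marrow phantom variant, seed 0."""
    return run_human_seed(0, marrow=True)


@pytest.fixture(scope="session")
def macaque_suite():
    """5-seed strong-bias macaque suite (bias correction on)."""
    return [run_macaque_seed(s) for s in MACAQUE_SEEDS]


@pytest.fixture(scope="session")
def human_seed0():
    """Full pipeline result + phantom for seed 0, reused by example tests."""
    spec = human_phantom_spec(0)
    vol, truth = make_phantom(spec)
    res = extract_brain_human(vol, HumanParams(), smooth=True)
    return {"spec": spec, "vol": vol, "truth": truth, "res": res}


@pytest.fixture(scope="session")
def macaque_seed0():
    spec = macaque_phantom_spec(0, bias_amp=0.5)
    vol, truth = make_phantom(spec)
    res = extract_brain_macaque(vol, MacaqueParams(), bias_correct=True)
    return {"spec": spec, "vol": vol, "truth": truth, "res": res}
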