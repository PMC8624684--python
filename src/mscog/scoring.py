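"""Cognitive-impairment classification from per-test z-scores.

A test is failed when its z-score lies strictly below -1.5 (i.e. more than
1.5 SD below the normative mean). A cognitive domain is impaired when at
least one of its tests is failed; global cognitive impairment requires at
least two failed tests, counted across all domains (the two failures may sit
in the same domain or in different ones).
"""

from __future__ import annotations

import math
from typing import Mapping

import numpy as np
import pandas as pd

from .simulate import DEFAULT_DOMAIN_MAP, _DOMAIN_LABEL

FAILURE_THRESHOLD = -1.5

DOMAINS = ("verbal_memory", "visual_memory", "attention_ips", "semantic_fluency")


def is_failed(z: float, threshold: float = FAILURE_THRESHOLD) -> bool:
    """True iff the z-score lies strictly below the failure threshold."""
    if not math.isfinite(z):
        raise ValueError(f"z-score must be finite, got {z!r}")
    return z < threshold


def _failed_tests(
    scores: Mapping[str, float],
    domain_map: Mapping[str, str],
    threshold: float,
) -> dict[str, list[str]]:
    failed: dict[str, list[str]] = {d: [] for d in dict.fromkeys(domain_map.values())}
    for test, domain in domain_map.items():
        if test not in scores:
            raise ValueError(f"missing score for test {test!r}")
        if is_failed(float(scores[test]), threshold):
            failed[domain].append(test)
    return failed


def classify_domain(
    scores: Mapping[str, float],
    domain: str,
    domain_map: Mapping[str, str] = DEFAULT_DOMAIN_MAP,
    threshold: float = FAILURE_THRESHOLD,
) -> bool:
    """Domain impairment: at least one failed test assessing that domain."""
    if domain not in set(domain_map.values()):
        raise ValueError(f"unknown domain {domain!r}")
    failed = _failed_tests(scores, domain_map, threshold)
    return len(failed[domain]) >= 1


def classify_global(
    scores: Mapping[str, float],
    domain_map: Mapping[str, str] = DEFAULT_DOMAIN_MAP,
    threshold: float = FAILURE_THRESHOLD,
) -> bool:
    """Global impairment: >=2 failed tests across the same or different domains."""
    if not domain_map:
        raise ValueError("empty test panel")
    failed = _failed_tests(scores, domain_map, threshold)
    return sum(len(v) for v in failed.values()) >= 2


def score_panel(
    test_scores: pd.DataFrame,
    domain_map: Mapping[str, str] = DEFAULT_DOMAIN_MAP,
    threshold: float = FAILURE_THRESHOLD,
) -> pd.DataFrame:
    """Apply the impairment rules to a per-test score table.

    Parameters
    ----------
    test_scores
        One row per subject with a ``subject_id`` column and one column per
        test named in ``domain_map``.

    Returns
    -------
    DataFrame with columns ``subject_id, ci_global, ci_verbal, ci_visual,
    ci_attn_ips, ci_fluency`` (0/1).
    """
    values = test_scores[list(domain_map)].to_numpy(dtype=float)
    if not np.isfinite(values).all():
        raise ValueError("test z-scores must be finite")
    fails = values < threshold
    tests = list(domain_map)
    out = pd.DataFrame({"subject_id": test_scores["subject_id"].to_numpy()})
    out["ci_global"] = (fails.sum(axis=1) >= 2).astype(int)
    for domain in DOMAINS:
        cols = [i for i, t in enumerate(tests) if domain_map[t] == domain]
        label = _DOMAIN_LABEL[domain]
        if cols:
            out[label] = fails[:, cols].any(axis=1).astype(int)
        else:
            out[label] = 0
    return out
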