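import math

import numpy as np
import pytest

from fspscan import FamilyAnnotation, MultipleAlignment


@pytest.fixture
def toy_alignment() -> MultipleAlignment:
    """Two families of two sequences; column 3 is family-diagnostic."""
    return MultipleAlignment(
        ids=["a1", "a2", "b1", "b2"],
        rows=["MKHA", "MKHA", "MKFA", "MKFA"],
    )


@pytest.fixture
def toy_annotation(toy_alignment) -> FamilyAnnotation:
    return FamilyAnnotation(
        {"a1": "famA", "a2": "famA", "b1": "famB", "b2": "famB"}
    )


def mi_bruteforce(per_family_counts: dict[str, dict[str, int]]) -> float:
    """Independent oracle: direct double summation of the plug-in MI.

    sum over residues a and families f of p(a,f) * log2(p(a,f)/(p(a)p(f))),
    computed with scalar arithmetic only.
    """
    n = sum(c for fam in per_family_counts.values() for c in fam.values())
    if n == 0:
        return 0.0
    residues = sorted({r for fam in per_family_counts.values() for r in fam})
    p_fam = {f: sum(cs.values()) / n for f, cs in per_family_counts.items()}
    p_res = {
        r: sum(cs.get(r, 0) for cs in per_family_counts.values()) / n
        for r in residues
    }
    mi = 0.0
    for f, cs in per_family_counts.items():
        for r, c in cs.items():
            if c == 0:
                continue
            p_joint = c / n
            mi += p_joint * math.log2(p_joint / (p_res[r] * p_fam[f]))
    return mi


def random_profile_counts(
    rng: np.random.Generator, max_families: int = 4, max_residues: int = 6
) -> dict[str, dict[str, int]]:
    """Random small per-family count table (some cells empty)."""
    n_fam = int(rng.integers(2, max_families + 1))
    n_res = int(rng.integers(2, max_residues + 1))
    residues = list("ACDEFGHIKLMNPQRSTVWY"[:n_res])
    out: dict[str, dict[str, int]] = {}
    for i in range(n_fam):
        counts = {
            r: int(rng.integers(0, 11))
            for r in residues
            if rng.random() < 0.8
        }
        out[f"fam{i + 1}"] = {r: c for r, c in counts.items() if c > 0}
    # guarantee at least one observation overall
    if not any(out.values()):
        out["fam1"] = {residues[0]: 1}
    return out
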