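"""Column statistics: conservation, family-specificity, significance.

For every alignment column we build a profile of residue counts, overall and
per family.  Superfamily conservation is the frequency of the most common
residue; family-specificity is scored as the plug-in mutual information (MI,
base 2) between residue identity and family label over the column's non-gap,
non-ambiguous observations.  Significance comes from a label-permutation
null: family labels are shuffled across sequences B times — one shared
permutation per iteration for all columns, which preserves the joint null
across columns — and a one-sided permutation p-value is assigned per column.
Benjamini–Hochberg false-discovery-rate control is then applied across all
non-masked columns, and each column receives exactly one verdict:
``masked`` (too gappy), ``conserved``, ``conserved_with_exceptions``,
``fsp`` or ``variable``.

The statistic reported is named "plug-in MI + label-permutation null + BH
FDR" in output provenance; no equivalence with any other subfamily-analysis
statistic is claimed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import rel_entr
from scipy.stats import entropy
from statsmodels.stats.multitest import multipletests

from .alignment import (
    AMINO_ACIDS,
    AlignmentError,
    FamilyAnnotation,
    MultipleAlignment,
    ReferenceNumbering,
    map_column_to_reference,
)

_LN2 = np.log(2.0)
#: float tolerance when comparing permuted MI against observed MI: two
#: contingency tables that are mathematically equivalent must count as ties.
_MI_TIE_TOL = 1e-12

STATISTIC_NAME = "plug-in MI + label-permutation null + BH FDR"


@dataclass(frozen=True)
class ScanConfig:
    """Thresholds and permutation settings for position classification.

    conserved_min_freq:
        minimum overall consensus frequency for a plain ``conserved`` call
        (0.98 rather than literal invariance: near-invariant columns with a
        handful of deviant sequences still define superfamily-wide
        properties).
    exception_max_families:
        how many families may deviate in a ``conserved_with_exceptions``
        call (default 1, the pattern of a single family replacing an
        otherwise invariant residue).
    fsp_min_within_family_consensus:
        a family "speaks with one voice" at a column when its consensus
        residue reaches this within-family frequency (default 0.90).
    fsp_min_distinct_consensi:
        an FSP must show at least this many distinct family consensi.
    gap_mask_threshold:
        columns with a larger gap+ambiguity fraction are masked.
    n_permutations:
        B, the number of label permutations (>= 99 so that the smallest
        achievable p-value 1/(B+1) resolves q <= 0.05).
    """

    conserved_min_freq: float = 0.98
    exception_max_families: int = 1
    fsp_min_within_family_consensus: float = 0.90
    fsp_min_distinct_consensi: int = 2
    gap_mask_threshold: float = 0.50
    n_permutations: int = 1000
    fdr_q: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "conserved_min_freq",
            "fsp_min_within_family_consensus",
            "gap_mask_threshold",
            "fdr_q",
        ):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise ValueError(f"{name} must be in (0, 1]")
        if self.n_permutations < 99:
            raise ValueError(
                "n_permutations must be >= 99 (p-value resolution too coarse)"
            )
        if self.exception_max_families < 0 or self.fsp_min_distinct_consensi < 2:
            raise ValueError("invalid classification thresholds")


@dataclass
class ColumnProfile:
    """Residue counts for one column, overall and per family.

    Gaps and ambiguity symbols are excluded from counts but included in
    ``gap_fraction``; ``n_effective`` is the number of counted observations.
    """

    column: int
    counts: dict[str, int]
    per_family_counts: dict[str, dict[str, int]]
    gap_fraction: float
    n_effective: int


@dataclass
class PositionClassification:
    """Final verdict for one column.

    ``category`` is one of ``conserved``, ``conserved_with_exceptions``,
    ``fsp``, ``variable``, ``masked``.  ``ref_labels`` maps each family to
    the reference-numbered residue of its representative at this column
    (``"N/A"`` for a gap).  p/q/z are NaN for masked columns, which never
    enter the multiple-testing stage.
    """

    column: int
    category: str
    consensus: str | None
    conservation: float
    mi: float
    nmi: float
    p_value: float
    q_value: float
    z_score: float
    exception_families: list[str] = field(default_factory=list)
    ref_labels: dict[str, str] = field(default_factory=dict)


@dataclass
class PermutationResult:
    """Per-column observed MI with permutation p-values and z-scores."""

    mi_obs: np.ndarray
    p_values: np.ndarray
    z_scores: np.ndarray
    n_permutations: int


# ---------------------------------------------------------------------------
# Profiles and scalar statistics


def column_profile(
    alignment: MultipleAlignment, annotation: FamilyAnnotation, column: int
) -> ColumnProfile:
    """Count residues at a 1-based column, overall and per family."""
    if not (1 <= column <= alignment.n_columns):
        raise AlignmentError(
            f"column {column} out of range 1..{alignment.n_columns}"
        )
    counts: dict[str, int] = {}
    per_family: dict[str, dict[str, int]] = {f: {} for f in annotation.families}
    n_missing = 0
    for sid, row in zip(alignment.ids, alignment.rows):
        ch = row[column - 1]
        fam = annotation.labels.get(sid)
        if fam is None:
            raise AlignmentError(f"sequence {sid} not annotated")
        if ch in AMINO_ACIDS:
            counts[ch] = counts.get(ch, 0) + 1
            per_family[fam][ch] = per_family[fam].get(ch, 0) + 1
        else:  # gap or ambiguity symbol: missing observation
            n_missing += 1
    return ColumnProfile(
        column=column,
        counts=counts,
        per_family_counts=per_family,
        gap_fraction=n_missing / alignment.n_sequences,
        n_effective=sum(counts.values()),
    )


def consensus_residue(counts: dict[str, int]) -> str | None:
    """Most common residue; ties broken alphabetically; None if empty."""
    if not counts:
        return None
    top = max(counts.values())
    return min(r for r, c in counts.items() if c == top)


def conservation_score(profile: ColumnProfile) -> float:
    """Frequency of the most common residue among effective observations."""
    if profile.n_effective == 0:
        raise AlignmentError(
            f"column {profile.column} has no residue observations; "
            "conservation is undefined (column must be masked)"
        )
    return max(profile.counts.values()) / profile.n_effective


def mutual_information(profile: ColumnProfile) -> tuple[float, float]:
    """Plug-in MI (bits) between residue and family, and its normalization.

    Computed over the column's non-gap, non-ambiguous observations.  The
    normalized value is ``mi / min(H(residue), H(family))`` and defined as 0
    when either entropy vanishes.
    """
    if len(profile.per_family_counts) < 2:
        raise AlignmentError("mutual information requires >= 2 families")
    families = list(profile.per_family_counts)
    residues = sorted(profile.counts)
    joint = np.zeros((len(residues), len(families)))
    for j, fam in enumerate(families):
        for i, res in enumerate(residues):
            joint[i, j] = profile.per_family_counts[fam].get(res, 0)
    n = joint.sum()
    if n == 0:
        return 0.0, 0.0
    p = joint / n
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    mi = float(rel_entr(p, px * py).sum() / _LN2)
    h_res = float(entropy(px.ravel(), base=2))
    h_fam = float(entropy(py.ravel(), base=2))
    h_min = min(h_res, h_fam)
    nmi = mi / h_min if h_min > 0 else 0.0
    return mi, nmi


# ---------------------------------------------------------------------------
# Vectorized column MI over the whole alignment


def _observations(alignment: MultipleAlignment):
    """Flattened (sequence, column, residue-code) triples of effective cells."""
    codes = alignment.codes()
    seq_idx, col_idx = np.nonzero(codes >= 0)
    return seq_idx, col_idx, codes[seq_idx, col_idx].astype(np.int64)


def _mi_per_column(
    col_idx: np.ndarray,
    res_codes: np.ndarray,
    fam_codes_per_obs: np.ndarray,
    n_columns: int,
    n_families: int,
) -> np.ndarray:
    """MI (bits) of every column for one assignment of family labels."""
    n_res = len(AMINO_ACIDS)
    flat = (col_idx * n_res + res_codes) * n_families + fam_codes_per_obs
    counts = np.bincount(
        flat, minlength=n_columns * n_res * n_families
    ).reshape(n_columns, n_res, n_families).astype(float)
    n = counts.sum(axis=(1, 2), keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, counts / np.maximum(n, 1.0), 0.0)
    px = p.sum(axis=2, keepdims=True)
    py = p.sum(axis=1, keepdims=True)
    return rel_entr(p, px * py).sum(axis=(1, 2)) / _LN2


def observed_mi(
    alignment: MultipleAlignment, annotation: FamilyAnnotation
) -> np.ndarray:
    """Observed per-column MI (bits) between residue and family."""
    if annotation.n_families < 2:
        raise AlignmentError("mutual information requires >= 2 families")
    seq_idx, col_idx, res = _observations(alignment)
    fam = annotation.family_codes(alignment)
    return _mi_per_column(
        col_idx, res, fam[seq_idx], alignment.n_columns, annotation.n_families
    )


def permutation_significance(
    alignment: MultipleAlignment,
    annotation: FamilyAnnotation,
    config: ScanConfig,
) -> PermutationResult:
    """Permutation p-values and z-scores for every column's MI.

    Each of the B iterations applies one permutation of family labels across
    sequences to all columns simultaneously, preserving any inter-column
    dependence under the null.  ``p = (1 + #{b : mi_b >= mi_obs}) / (B + 1)``;
    ``z = (mi_obs - mean_b) / sd_b`` with z = 0 where sd_b = 0.
    Deterministic given ``config.seed``.
    """
    if annotation.n_families < 2:
        raise AlignmentError("permutation test requires >= 2 families")
    B = config.n_permutations
    seq_idx, col_idx, res = _observations(alignment)
    fam = annotation.family_codes(alignment)
    n_cols, n_fam = alignment.n_columns, annotation.n_families
    mi_obs = _mi_per_column(col_idx, res, fam[seq_idx], n_cols, n_fam)

    rng = np.random.default_rng(config.seed)
    count_ge = np.zeros(n_cols, dtype=np.int64)
    sum_mi = np.zeros(n_cols)
    sum_sq = np.zeros(n_cols)
    for _ in range(B):
        perm_fam = fam[rng.permutation(len(fam))]
        mi_b = _mi_per_column(col_idx, res, perm_fam[seq_idx], n_cols, n_fam)
        count_ge += mi_b >= mi_obs - _MI_TIE_TOL
        sum_mi += mi_b
        sum_sq += mi_b * mi_b
    p = (1.0 + count_ge) / (B + 1.0)
    mean = sum_mi / B
    var = np.maximum(sum_sq / B - mean * mean, 0.0)
    sd = np.sqrt(var)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(sd > 0, (mi_obs - mean) / np.maximum(sd, 1e-300), 0.0)
    return PermutationResult(mi_obs, p, z, B)


# ---------------------------------------------------------------------------
# Classification


def _family_consensi(
    profile: ColumnProfile,
) -> tuple[dict[str, str], dict[str, float]]:
    """Per-family consensus residue and frequency (families with data only)."""
    consensi: dict[str, str] = {}
    freqs: dict[str, float] = {}
    for fam, counts in profile.per_family_counts.items():
        res = consensus_residue(counts)
        if res is None:
            continue
        consensi[fam] = res
        freqs[fam] = counts[res] / sum(counts.values())
    return consensi, freqs


def classify_positions(
    alignment: MultipleAlignment,
    annotation: FamilyAnnotation,
    numberings: dict[str, ReferenceNumbering] | None = None,
    config: ScanConfig | None = None,
    permutation: PermutationResult | None = None,
) -> list[PositionClassification]:
    """Classify every column of the alignment.

    Verdict order per column: ``masked`` if the gap+ambiguity fraction
    exceeds the mask threshold; ``conserved`` if the overall consensus
    frequency reaches ``conserved_min_freq``; ``conserved_with_exceptions``
    if the overall consensus is the confident within-family consensus in all
    but at most ``exception_max_families`` families (deviating families are
    listed); ``fsp`` if the column is significant after BH FDR control and
    shows at least ``fsp_min_distinct_consensi`` distinct family consensi
    with at least two confidently conserved families; otherwise
    ``variable``.  BH q-values are computed over all non-masked columns.
    """
    config = config or ScanConfig()
    numberings = numberings or {}
    for fam in numberings:
        if fam not in annotation.families:
            raise AlignmentError(f"numbering given for unknown family {fam}")
    if permutation is None:
        permutation = permutation_significance(alignment, annotation, config)

    n_cols = alignment.n_columns
    profiles = [
        column_profile(alignment, annotation, c) for c in range(1, n_cols + 1)
    ]
    masked = np.array(
        [pr.gap_fraction > config.gap_mask_threshold or pr.n_effective == 0
         for pr in profiles]
    )
    q = np.full(n_cols, np.nan)
    if (~masked).any():
        _, q_vals, _, _ = multipletests(
            permutation.p_values[~masked], method="fdr_bh"
        )
        q[~masked] = q_vals

    n_families = annotation.n_families
    results: list[PositionClassification] = []
    for j, pr in enumerate(profiles):
        col = j + 1
        ref_labels = {
            fam: map_column_to_reference(alignment, num, col)
            for fam, num in numberings.items()
        }
        if masked[j]:
            results.append(
                PositionClassification(
                    column=col, category="masked", consensus=None,
                    conservation=float("nan"), mi=float(permutation.mi_obs[j]),
                    nmi=float("nan"), p_value=float("nan"),
                    q_value=float("nan"), z_score=float("nan"),
                    ref_labels=ref_labels,
                )
            )
            continue
        cons = consensus_residue(pr.counts)
        conservation = conservation_score(pr)
        mi, nmi = mutual_information(pr)
        consensi, freqs = _family_consensi(pr)
        confident = {
            f for f, fr in freqs.items()
            if fr >= config.fsp_min_within_family_consensus
        }
        agreeing = {f for f in confident if consensi[f] == cons}
        base = dict(
            column=col, consensus=cons, conservation=conservation,
            mi=mi, nmi=nmi, p_value=float(permutation.p_values[j]),
            q_value=float(q[j]), z_score=float(permutation.z_scores[j]),
            ref_labels=ref_labels,
        )
        exceptions_candidate = [
            f for f in annotation.families if f not in agreeing
        ]
        if conservation >= config.conserved_min_freq:
            category, exceptions = "conserved", []
        elif len(agreeing) >= n_families - config.exception_max_families and (
            len(agreeing) > len(exceptions_candidate)
        ):
            # the agreeing families must form a strict majority, otherwise
            # (e.g. 1-vs-1 with two families) there is no consensus to except
            # from; an empty exception list is plain conservation
            exceptions = exceptions_candidate
            category = "conserved_with_exceptions" if exceptions else "conserved"
        elif (
            q[j] <= config.fdr_q
            and len(set(consensi.values())) >= config.fsp_min_distinct_consensi
            and len(confident) >= 2
        ):
            category, exceptions = "fsp", []
        else:
            category, exceptions = "variable", []
        results.append(
            PositionClassification(
                category=category, exception_families=exceptions, **base
            )
        )
    return results


def write_positions_tsv(
    classifications: list[PositionClassification],
    families: list[str],
    path,
) -> None:
    """Results table, one row per column, with per-family reference labels."""
    def fmt(x: float) -> str:
        return "NA" if np.isnan(x) else f"{x:.6g}"

    with open(path, "w") as fh:
        header = [
            "column", "class", "consensus", "conservation", "mi", "nmi",
            "p", "q", "z", "exception_families",
        ] + [f"ref_{f}" for f in families]
        fh.write("\t".join(header) + "\n")
        for pc in classifications:
            row = [
                str(pc.column), pc.category, pc.consensus or "NA",
                fmt(pc.conservation), fmt(pc.mi), fmt(pc.nmi),
                fmt(pc.p_value), fmt(pc.q_value), fmt(pc.z_score),
                ",".join(pc.exception_families) or "-",
            ] + [pc.ref_labels.get(f, "NA") for f in families]
            fh.write("\t".join(row) + "\n")
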