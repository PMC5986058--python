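"""Per-family sequence-set cleaning: redundancy and outlier removal.

Both filters compare every family member against sequences already retained
(or against the family representative) and record a machine-checkable reason
for every removal, so a report line plus the configuration reproduces the
decision.  Filters are deterministic in input order and idempotent.
"""

from __future__ import annotations

from dataclasses import dataclass

from .alignment import (
    AlignmentError,
    FilterConfig,
    MultipleAlignment,
    UNDEFINED_BITS,
    bits_per_column,
    load_substitution_matrix,
    pairwise_identity,
    ungapped_length,
)


@dataclass
class FilterReport:
    """Outcome of one filter pass over one family's rows.

    ``removed`` holds ``(seq_id, reason)`` pairs; reasons are of the form
    ``redundant_with:<id>``, ``low_bits_per_column:<value>``,
    ``length_diff:<fraction>`` or ``over_cap``.
    """

    retained_ids: list[str]
    removed: list[tuple[str, str]]
    config_used: FilterConfig

    @property
    def removed_ids(self) -> list[str]:
        return [sid for sid, _ in self.removed]


def _family_order(alignment: MultipleAlignment, representative_id: str) -> list[str]:
    if representative_id not in alignment.ids:
        raise AlignmentError(
            f"representative {representative_id} absent from family rows"
        )
    return [representative_id] + [
        s for s in alignment.ids if s != representative_id
    ]


def redundancy_filter(
    family: MultipleAlignment,
    representative_id: str,
    config: FilterConfig | None = None,
) -> FilterReport:
    """Collapse near-identical sequences within one family.

    Greedy sweep in input order with the representative first: a sequence is
    removed iff its pairwise identity with some already-retained sequence is
    ``>= identity_threshold`` (default 0.95, so 95%-identical pairs are
    collapsed).  The representative is always retained.
    """
    config = config or FilterConfig()
    retained: list[str] = []
    removed: list[tuple[str, str]] = []
    for sid in _family_order(family, representative_id):
        row = family.row(sid)
        hit = None
        for kept in retained:
            if pairwise_identity(row, family.row(kept)) >= config.identity_threshold:
                hit = kept
                break
        if hit is None:
            retained.append(sid)
        else:
            removed.append((sid, f"redundant_with:{hit}"))
    return FilterReport(retained, removed, config)


def outlier_filter(
    family: MultipleAlignment,
    representative_id: str,
    config: FilterConfig | None = None,
) -> FilterReport:
    """Remove family members too dissimilar to the representative.

    A sequence is removed iff its average substitution score against the
    representative falls below ``min_bits_per_column`` (default 0.5 bits) or
    its ungapped length differs from the representative's by more than
    ``max_length_diff`` (default 20%, strict inequality: exactly 20% is
    retained).  If more than ``max_seqs_per_family`` sequences survive, the
    first ``max_seqs_per_family`` in sweep order are kept and the rest are
    dropped with reason ``over_cap``.
    """
    config = config or FilterConfig()
    matrix = load_substitution_matrix(config.substitution_matrix_name)
    rep_row = family.row(representative_id)
    rep_len = ungapped_length(rep_row)
    if rep_len == 0:
        raise AlignmentError("representative has length 0")

    retained: list[str] = []
    removed: list[tuple[str, str]] = []
    for sid in _family_order(family, representative_id):
        if sid == representative_id:
            retained.append(sid)
            continue
        row = family.row(sid)
        bits = bits_per_column(row, rep_row, matrix)
        if bits == UNDEFINED_BITS or bits < config.min_bits_per_column:
            shown = "undefined" if bits == UNDEFINED_BITS else f"{bits:.4f}"
            removed.append((sid, f"low_bits_per_column:{shown}"))
            continue
        length_diff = abs(ungapped_length(row) - rep_len) / rep_len
        if length_diff > config.max_length_diff:
            removed.append((sid, f"length_diff:{length_diff:.4f}"))
            continue
        retained.append(sid)
    if len(retained) > config.max_seqs_per_family:
        for sid in retained[config.max_seqs_per_family :]:
            removed.append((sid, "over_cap"))
        retained = retained[: config.max_seqs_per_family]
    return FilterReport(retained, removed, config)


def clean_family(
    family: MultipleAlignment,
    representative_id: str,
    config: FilterConfig | None = None,
) -> tuple[MultipleAlignment, list[FilterReport]]:
    """Outlier filter followed by redundancy filter (pipeline order).

    Outliers are dropped first so that redundancy among discarded outliers
    never influences which sequences survive.
    """
    config = config or FilterConfig()
    out_rep = outlier_filter(family, representative_id, config)
    surviving = family.subset(out_rep.retained_ids)
    red_rep = redundancy_filter(surviving, representative_id, config)
    return surviving.subset(red_rep.retained_ids), [out_rep, red_rep]
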