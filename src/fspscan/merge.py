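"""Merge per-family sub-alignments into one superfamily alignment.

The guide is a core alignment containing exactly one representative per
family (in practice derived from 3D superposition of representative
structures; consumed here as an aligned FASTA input).  The merge places each
family's residues into the core's column system via its representative:

* a sub-alignment column in which the representative carries its *i*-th
  residue maps onto the core column holding that same residue;
* sub-alignment columns in which the representative is gapped (insertions
  relative to the representative) become family-private insert columns in
  which every other family carries gaps;
* core columns in which a family's representative is gapped are kept, with
  that family's rows gapped.

Insert blocks are left-anchored: they follow immediately after the core
column of the preceding representative residue (a virtual column 0 for
leading insertions).  Blocks of different families at the same anchor appear
in family input order.  No attempt is made to align two families' insertions
to each other — without structural information such columns are not
comparable.
"""

from __future__ import annotations

from dataclasses import dataclass

from .alignment import GAP, AlignmentError, MultipleAlignment


@dataclass
class MergeFixture:
    """Inputs of one merge: guide core, per-family subs, representative map."""

    core: MultipleAlignment
    subs: dict[str, MultipleAlignment]
    representative_of: dict[str, str]

    def __post_init__(self) -> None:
        if set(self.subs) != set(self.representative_of):
            raise AlignmentError("subs and representative_of disagree on families")
        for fam, sub in self.subs.items():
            rep = self.representative_of[fam]
            core_seq = self.core.row(rep).replace(GAP, "")
            sub_seq = sub.row(rep).replace(GAP, "")
            if core_seq != sub_seq:
                raise AlignmentError(
                    f"representative {rep} of family {fam} differs between "
                    "core and sub-alignment"
                )


@dataclass
class MergedAlignment:
    """Merge output: the superfamily alignment plus column provenance.

    ``provenance[j]`` is ``("core", c)`` for the core column ``c`` (1-based)
    or ``("insert", family, anchor, offset)`` for the ``offset``-th column of
    the family's insert block anchored after core column ``anchor`` (0 for
    leading insertions).
    """

    alignment: MultipleAlignment
    provenance: list[tuple]


def merge_by_core(fixture: MergeFixture) -> MergedAlignment:
    """Merge family sub-alignments using the core alignment as the guide.

    Within-family residue correspondences are preserved exactly (every sub
    column maps injectively and order-preservingly into the output) and the
    representatives' mutual correspondences are exactly those of the core.
    """
    core = fixture.core
    if core.n_columns < 1 or core.n_sequences < 1:
        raise AlignmentError("empty core alignment")
    families = list(fixture.subs)

    # Per family: core column (1-based) of each representative residue, and
    # per sub column either the residue index it holds or the insert anchor.
    sub_col_target: dict[str, list[tuple]] = {}
    res_core_col: dict[str, list[int]] = {}
    inserts: dict[tuple[str, int], list[int]] = {}  # (family, anchor) -> sub cols
    for fam in families:
        rep = fixture.representative_of[fam]
        core_row = core.row(rep)
        cols = [c + 1 for c, ch in enumerate(core_row) if ch != GAP]
        res_core_col[fam] = cols
        sub_row = fixture.subs[fam].row(rep)
        targets: list[tuple] = []
        n_res = 0
        for j, ch in enumerate(sub_row):
            if ch != GAP:
                targets.append(("res", n_res))
                n_res += 1
            else:
                anchor = cols[n_res - 1] if n_res > 0 else 0
                key = (fam, anchor)
                inserts.setdefault(key, []).append(j)
                targets.append(("ins", anchor, len(inserts[key]) - 1))
        sub_col_target[fam] = targets

    # Output column skeleton: leading inserts, then each core column followed
    # by the insert blocks anchored at it, in family input order.
    provenance: list[tuple] = []
    for anchor in range(0, core.n_columns + 1):
        if anchor > 0:
            provenance.append(("core", anchor))
        for fam in families:
            for offset in range(len(inserts.get((fam, anchor), ()))):
                provenance.append(("insert", fam, anchor, offset))

    width = len(provenance)
    # Inverse maps for fast row assembly.
    core_out_col = {}
    insert_out_col = {}
    for out_j, tag in enumerate(provenance):
        if tag[0] == "core":
            core_out_col[tag[1]] = out_j
        else:
            insert_out_col[(tag[1], tag[2], tag[3])] = out_j

    ids: list[str] = []
    rows: list[str] = []
    for fam in families:
        sub = fixture.subs[fam]
        cols = res_core_col[fam]
        targets = sub_col_target[fam]
        for sid, sub_row in zip(sub.ids, sub.rows):
            out = [GAP] * width
            for j, ch in enumerate(sub_row):
                tgt = targets[j]
                if tgt[0] == "res":
                    out[core_out_col[cols[tgt[1]]]] = ch
                else:
                    out[insert_out_col[(fam, tgt[1], tgt[2])]] = ch
            ids.append(sid)
            rows.append("".join(out))
    return MergedAlignment(MultipleAlignment(ids, rows), provenance)


def induced_correspondences(
    alignment: MultipleAlignment, id_a: str, id_b: str
) -> list[tuple[int, int]]:
    """Residue-index pairs aligned between two rows of one alignment.

    Brute-force extractor used to state (and test) merge fidelity: the pair
    ``(i, k)`` means residue ``i`` of ``id_a`` is in the same column as
    residue ``k`` of ``id_b`` (0-based ungapped indices).
    """
    row_a = alignment.row(id_a)
    row_b = alignment.row(id_b)
    pairs = []
    i = k = 0
    for a, b in zip(row_a, row_b):
        if a != GAP and b != GAP:
            pairs.append((i, k))
        if a != GAP:
            i += 1
        if b != GAP:
            k += 1
    return pairs


def write_provenance(provenance: list[tuple], path) -> None:
    """Write column provenance as TSV: column, kind, detail."""
    with open(path, "w") as fh:
        fh.write("column\tkind\tdetail\n")
        for j, tag in enumerate(provenance, start=1):
            if tag[0] == "core":
                fh.write(f"{j}\tcore\t{tag[1]}\n")
            else:
                _, fam, anchor, offset = tag
                fh.write(f"{j}\tinsert\t{fam}:after_core_{anchor}:{offset}\n")
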