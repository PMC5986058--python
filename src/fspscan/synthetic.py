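"""Synthetic alignments with known planted structure.

Three generators cover the pipeline's test needs:

* :func:`generate_alignment` — a multi-family alignment with planted
  globally conserved columns (optionally with rare deviations), planted
  exception columns (one family carries its own residue while all others
  share the majority residue), planted family-specific columns (each family
  conserves its own residue) and i.i.d. background columns, plus per-cell
  gaps.  The ground truth of every planted column is recorded and returned.
* :func:`generate_merge_fixture` — a core alignment of representatives plus
  per-family sub-alignments with planted insertions, for merge testing.
* :func:`generate_family_alignment` — an alignment with tunable within- and
  between-family identity (no planted columns), for clustering tests.

Families are generated i.i.d. within each family, without a phylogeny; real
families are tree-correlated, which inflates residue–family association
relative to this model (see the package's methods documentation).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alignment import AMINO_ACIDS, FamilyAnnotation, MultipleAlignment
from .merge import MergeFixture

_N_RES = len(AMINO_ACIDS)
_RES_TO_CODE = {aa: i for i, aa in enumerate(AMINO_ACIDS)}


@dataclass
class SynthConfig:
    """Planted-structure recipe for :func:`generate_alignment`.

    Columns are 1-based.  ``conserved_columns`` holds ``(column, residue,
    deviation_rate)``; ``exception_columns`` holds ``(column,
    majority_residue, deviating_family, its_residue)`` and is planted
    noise-free; ``fsp_columns`` holds ``(column, {family: residue},
    deviation_rate)``.  All remaining columns are i.i.d. background.
    """

    n_families: int
    seqs_per_family: int
    n_columns: int
    conserved_columns: list[tuple[int, str, float]] = field(default_factory=list)
    exception_columns: list[tuple[int, str, str, str]] = field(default_factory=list)
    fsp_columns: list[tuple[int, dict[str, str], float]] = field(default_factory=list)
    background_distribution: dict[str, float] | None = None
    gap_rate: float = 0.0
    gap_protect_planted: bool = True
    seed: int = 0

    @property
    def family_labels(self) -> list[str]:
        return [f"fam{i + 1}" for i in range(self.n_families)]

    def __post_init__(self) -> None:
        if self.n_families < 1 or self.seqs_per_family < 1 or self.n_columns < 1:
            raise ValueError("sizes must be positive")
        planted = (
            [c for c, _, _ in self.conserved_columns]
            + [c for c, _, _, _ in self.exception_columns]
            + [c for c, _, _ in self.fsp_columns]
        )
        if len(planted) != len(set(planted)):
            raise ValueError("planted column sets overlap")
        if any(not (1 <= c <= self.n_columns) for c in planted):
            raise ValueError("planted column out of range")
        fams = set(self.family_labels)
        for _, _, fam, _ in self.exception_columns:
            if fam not in fams:
                raise ValueError(f"unknown deviating family {fam}")
        for c, fam_map, _ in self.fsp_columns:
            if set(fam_map) != fams:
                raise ValueError(f"fsp column {c} must map every family")
            if len(set(fam_map.values())) < 2:
                raise ValueError(f"fsp column {c} needs >= 2 distinct residues")
        if self.background_distribution is not None:
            total = sum(self.background_distribution.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError("background_distribution must sum to 1")
        if not (0.0 <= self.gap_rate < 1.0):
            raise ValueError("gap_rate must be in [0, 1)")


@dataclass
class SyntheticGroundTruth:
    """Per-column planted roles, parallel to the generated alignment."""

    roles: list[str]  # per column: conserved | exception | fsp | background
    planted: dict[int, dict[str, str]]  # column -> family -> planted residue
    config: SynthConfig

    def columns_with_role(self, role: str) -> list[int]:
        return [j + 1 for j, r in enumerate(self.roles) if r == role]

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("column\trole\tplanted\n")
            for j, role in enumerate(self.roles, start=1):
                detail = ";".join(
                    f"{f}:{r}" for f, r in self.planted.get(j, {}).items()
                ) or "-"
                fh.write(f"{j}\t{role}\t{detail}\n")


def _deviate(rng: np.random.Generator, base: np.ndarray, rate: float) -> np.ndarray:
    """Replace each entry with a uniformly chosen *different* residue at `rate`."""
    out = base.copy()
    hit = rng.random(base.shape) < rate
    if hit.any():
        shift = rng.integers(1, _N_RES, size=int(hit.sum()))
        out[hit] = (out[hit] + shift) % _N_RES
    return out


def generate_alignment(
    config: SynthConfig,
) -> tuple[MultipleAlignment, FamilyAnnotation, SyntheticGroundTruth]:
    """Generate a planted-structure alignment; deterministic given the seed."""
    rng = np.random.default_rng(config.seed)
    fams = config.family_labels
    n_seq = config.n_families * config.seqs_per_family
    fam_of_row = np.repeat(np.arange(config.n_families), config.seqs_per_family)

    if config.background_distribution is None:
        probs = np.full(_N_RES, 1.0 / _N_RES)
    else:
        probs = np.zeros(_N_RES)
        for res, p in config.background_distribution.items():
            probs[_RES_TO_CODE[res]] = p

    codes = rng.choice(_N_RES, size=(n_seq, config.n_columns), p=probs)
    roles = ["background"] * config.n_columns
    planted: dict[int, dict[str, str]] = {}

    for col, res, eps in config.conserved_columns:
        base = np.full(n_seq, _RES_TO_CODE[res])
        codes[:, col - 1] = _deviate(rng, base, eps)
        roles[col - 1] = "conserved"
        planted[col] = {f: res for f in fams}
    for col, majority, dev_fam, dev_res in config.exception_columns:
        base = np.full(n_seq, _RES_TO_CODE[majority])
        base[fam_of_row == fams.index(dev_fam)] = _RES_TO_CODE[dev_res]
        codes[:, col - 1] = base
        roles[col - 1] = "exception"
        planted[col] = {
            f: (dev_res if f == dev_fam else majority) for f in fams
        }
    for col, fam_map, eps in config.fsp_columns:
        base = np.array([_RES_TO_CODE[fam_map[fams[f]]] for f in fam_of_row])
        codes[:, col - 1] = _deviate(rng, base, eps)
        roles[col - 1] = "fsp"
        planted[col] = dict(fam_map)

    chars = np.array(list(AMINO_ACIDS))[codes]
    if config.gap_rate > 0:
        gap_mask = rng.random(codes.shape) < config.gap_rate
        if config.gap_protect_planted:
            for col in planted:
                gap_mask[:, col - 1] = False
        chars[gap_mask] = "-"

    ids = [
        f"{fams[f]}_s{i + 1}"
        for f in range(config.n_families)
        for i in range(config.seqs_per_family)
    ]
    rows = ["".join(r) for r in chars]
    alignment = MultipleAlignment(ids, rows)
    annotation = FamilyAnnotation(
        {sid: fams[f] for sid, f in zip(ids, fam_of_row)}
    )
    truth = SyntheticGroundTruth(roles=roles, planted=planted, config=config)
    return alignment, annotation, truth


def random_planted_config(
    rng: np.random.Generator,
    n_families: int,
    seqs_per_family: int,
    n_columns: int,
    n_fsp: int,
    n_conserved: int,
    n_exception: int = 0,
    fsp_deviation: float = 0.05,
    conserved_deviation: float = 0.01,
    gap_rate: float = 0.02,
    seed: int = 0,
) -> SynthConfig:
    """Draw a :class:`SynthConfig` with random planted columns and residues.

    FSP columns assign residues to families without replacement, the
    defining pattern of a family-specific position (conserved within each
    family, different between families).
    """
    n_planted = n_fsp + n_conserved + n_exception
    cols = rng.choice(n_columns, size=n_planted, replace=False) + 1
    fsp_cols, cons_cols, exc_cols = (
        cols[:n_fsp],
        cols[n_fsp : n_fsp + n_conserved],
        cols[n_fsp + n_conserved :],
    )
    fams = [f"fam{i + 1}" for i in range(n_families)]
    aa = list(AMINO_ACIDS)
    fsp = []
    for c in fsp_cols:
        picks = rng.choice(_N_RES, size=n_families, replace=False)
        fsp.append((int(c), {f: aa[p] for f, p in zip(fams, picks)}, fsp_deviation))
    conserved = [
        (int(c), aa[int(rng.integers(_N_RES))], conserved_deviation)
        for c in cons_cols
    ]
    exception = []
    for c in exc_cols:
        maj, dev = rng.choice(_N_RES, size=2, replace=False)
        dev_fam = fams[int(rng.integers(n_families))]
        exception.append((int(c), aa[int(maj)], dev_fam, aa[int(dev)]))
    return SynthConfig(
        n_families=n_families,
        seqs_per_family=seqs_per_family,
        n_columns=n_columns,
        conserved_columns=conserved,
        exception_columns=exception,
        fsp_columns=fsp,
        gap_rate=gap_rate,
        seed=seed,
    )


def generate_merge_fixture(
    n_families: int,
    core_length: int,
    insertions: list[tuple[int, int, int]],
    seed: int = 0,
    seqs_per_family: int = 3,
    core_gap_rate: float = 0.0,
) -> tuple[MergeFixture, int]:
    """Build a random merge fixture with planted insertions.

    ``insertions`` holds ``(family_index, anchor, width)``: a block of
    ``width`` columns inserted after the ``anchor``-th residue of that
    family's representative (anchor 0 = before the first residue).  Returns
    the fixture and the expected merged column count
    (core_length + total inserted width).
    """
    if core_length < 1 or n_families < 1:
        raise ValueError("sizes must be positive")
    rng = np.random.default_rng(seed)
    fams = [f"fam{i + 1}" for i in range(n_families)]
    aa = np.array(list(AMINO_ACIDS))

    core_rows = []
    rep_seqs = []
    for _ in range(n_families):
        row = aa[rng.integers(_N_RES, size=core_length)]
        if core_gap_rate > 0:
            gaps = rng.random(core_length) < core_gap_rate
            if gaps.all():
                gaps[int(rng.integers(core_length))] = False
            row = np.where(gaps, "-", row)
        core_rows.append("".join(row))
        rep_seqs.append("".join(ch for ch in row if ch != "-"))

    ins_by_family: dict[int, list[tuple[int, int]]] = {}
    for fam_i, anchor, width in insertions:
        if not (0 <= fam_i < n_families):
            raise ValueError(f"family index {fam_i} out of range")
        if not (0 <= anchor <= len(rep_seqs[fam_i])):
            raise ValueError(
                f"anchor {anchor} out of range for family {fams[fam_i]}"
            )
        if width < 1:
            raise ValueError("insertion width must be positive")
        ins_by_family.setdefault(fam_i, []).append((anchor, width))

    subs: dict[str, MultipleAlignment] = {}
    representative_of: dict[str, str] = {}
    rep_ids = [f"{fam}_rep" for fam in fams]
    for fam_i, fam in enumerate(fams):
        rep_seq = rep_seqs[fam_i]
        blocks = sorted(ins_by_family.get(fam_i, []))
        rep_row = []
        pos = 0
        for anchor, width in blocks:
            rep_row.append(rep_seq[pos:anchor])
            rep_row.append("-" * width)
            pos = anchor
        rep_row.append(rep_seq[pos:])
        rep_row = "".join(rep_row)
        width_sub = len(rep_row)
        rows = [rep_row]
        ids = [rep_ids[fam_i]]
        for s in range(seqs_per_family - 1):
            rows.append("".join(aa[rng.integers(_N_RES, size=width_sub)]))
            ids.append(f"{fam}_s{s + 1}")
        subs[fam] = MultipleAlignment(ids, rows)
        representative_of[fam] = rep_ids[fam_i]

    core = MultipleAlignment(rep_ids, core_rows)
    fixture = MergeFixture(core=core, subs=subs, representative_of=representative_of)
    expected_width = core_length + sum(w for _, _, w in insertions)
    return fixture, expected_width


def generate_family_alignment(
    n_families: int,
    seqs_per_family: int,
    n_columns: int,
    within_identity: float = 0.85,
    between_identity: float = 0.25,
    seed: int = 0,
) -> tuple[MultipleAlignment, FamilyAnnotation]:
    """Alignment with tunable within/between-family identity (no planting).

    Each family has a consensus derived from a shared ancestor; sequences
    copy their family consensus per site with a retention probability solved
    analytically so that expected pairwise identities match the requested
    values (uniform 20-residue background, no gaps).
    """
    t_sq = (20.0 * within_identity - 1.0) / 19.0
    if not (0.0 < t_sq <= 1.0):
        raise ValueError("within_identity infeasible for a 20-letter alphabet")
    q = (between_identity - (1.0 - t_sq) / 20.0) / t_sq
    a_sq = (20.0 * q - 1.0) / 19.0
    if not (0.0 <= a_sq <= 1.0):
        raise ValueError(
            "between_identity infeasible given within_identity"
        )
    t, a = np.sqrt(t_sq), np.sqrt(a_sq)

    rng = np.random.default_rng(seed)
    ancestor = rng.integers(_N_RES, size=n_columns)
    fams = [f"fam{i + 1}" for i in range(n_families)]
    ids, rows, labels = [], [], {}
    aa = np.array(list(AMINO_ACIDS))
    for fam in fams:
        keep = rng.random(n_columns) < a
        consensus = np.where(keep, ancestor, rng.integers(_N_RES, size=n_columns))
        for s in range(seqs_per_family):
            copy = rng.random(n_columns) < t
            seq = np.where(copy, consensus, rng.integers(_N_RES, size=n_columns))
            sid = f"{fam}_s{s + 1}"
            ids.append(sid)
            rows.append("".join(aa[seq]))
            labels[sid] = fam
    return MultipleAlignment(ids, rows), FamilyAnnotation(labels)
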