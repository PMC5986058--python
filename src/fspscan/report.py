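"""Pipeline orchestration and family-by-position report rendering.

The final deliverable of a scan is a table in the style of a superfamily
position report: one row per functional family (with its representative
protein), one column per reported alignment position — conserved positions
first, then family-specific positions ordered by descending permutation
z-score — and reference-numbered residue labels in the cells (``N/A`` where
the family's representative is gapped).

``run_scan`` drives the whole pipeline from a YAML-style config mapping:
optional per-family filtering, optional core-guided merge, family annotation
or specificity clustering, the position scan, and report rendering.  All
stage inputs are validated before any computation starts, and a fixed seed
makes the entire run, including every written TSV, byte-reproducible.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass, field
from importlib import metadata
from pathlib import Path

import pandas as pd
import yaml

from .alignment import (
    AlignmentError,
    FamilyAnnotation,
    FilterConfig,
    MultipleAlignment,
    ReferenceNumbering,
    read_alignment,
    read_family_annotation,
    write_alignment,
    write_family_annotation,
)
from .clustering import OBJECTIVE_NAME, cluster_specificity_groups
from .filters import clean_family
from .merge import MergeFixture, merge_by_core, write_provenance
from .stats import (
    STATISTIC_NAME,
    PositionClassification,
    ScanConfig,
    classify_positions,
    write_positions_tsv,
)


@dataclass
class ScanResultBundle:
    """Everything a scan produced: verdicts, rendered table, provenance."""

    classifications: list[PositionClassification]
    family_table: pd.DataFrame
    provenance: dict = field(default_factory=dict)


def _package_version() -> str:
    try:
        return metadata.version("fspscan")
    except metadata.PackageNotFoundError:  # pragma: no cover
        return "unknown"


def build_family_table(
    classifications: list[PositionClassification],
    alignment: MultipleAlignment,
    annotation: FamilyAnnotation,
    numberings: dict[str, ReferenceNumbering],
) -> pd.DataFrame:
    """Render the family x position table from computed classifications.

    Rows are families (index) with their representative id; columns are the
    conserved positions (including conserved-with-exceptions) in alignment
    order followed by FSPs by descending z-score; cells are the
    reference-numbered residues of each family's representative, ``N/A``
    at gaps.  Pure function of its inputs: nothing is recomputed.
    """
    from .alignment import map_column_to_reference

    missing = [f for f in annotation.families if f not in numberings]
    if missing:
        raise AlignmentError(
            "no representative numbering for families: " + ", ".join(missing)
        )
    conserved_cols = [
        pc.column
        for pc in classifications
        if pc.category in ("conserved", "conserved_with_exceptions")
    ]
    fsp_cols = [
        pc.column
        for pc in sorted(
            (pc for pc in classifications if pc.category == "fsp"),
            key=lambda pc: (-pc.z_score, pc.column),
        )
    ]
    data: dict[str, list[str]] = {"representative": []}
    col_names = [f"c{c}" for c in conserved_cols + fsp_cols]
    for name in col_names:
        data[name] = []
    for fam in annotation.families:
        num = numberings[fam]
        data["representative"].append(num.seq_id)
        for name, col in zip(col_names, conserved_cols + fsp_cols):
            data[name].append(
                map_column_to_reference(alignment, num, col)
            )
    return pd.DataFrame(data, index=pd.Index(annotation.families, name="family"))


def render_table_markdown(table: pd.DataFrame) -> str:
    """Human-readable markdown render of the family table."""
    return table.to_markdown()


# ---------------------------------------------------------------------------
# Pipeline driver


def _require_file(path: str | Path, what: str) -> Path:
    p = Path(path)
    if not p.is_file():
        raise AlignmentError(f"{what} not found: {p}")
    return p


def _read_representatives(path: str | Path) -> dict[str, str]:
    reps: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fam, sid = line.split("\t")
            reps[fam] = sid
    return reps


def _read_numberings(path: str | Path) -> dict[str, ReferenceNumbering]:
    """TSV ``family<TAB>seq_id<TAB>start_number``."""
    out: dict[str, ReferenceNumbering] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fam, sid, start = line.split("\t")
            out[fam] = ReferenceNumbering(seq_id=sid, start_number=int(start))
    return out


def _log(msg: str, quiet: bool) -> None:
    if not quiet:
        print(msg, file=sys.stderr)


def run_scan(config: dict, out_dir: str | Path, quiet: bool = True) -> ScanResultBundle:
    """Execute the pipeline described by a config mapping.

    Config sections (all paths relative to the caller's cwd):

    * ``inputs``: either ``alignment`` (merged aligned FASTA) or ``core`` +
      ``subs`` (mapping family -> FASTA) + ``representatives`` (mapping
      family -> seq id); optionally ``families`` (annotation TSV).
    * ``filters``: ``enabled`` plus any :class:`FilterConfig` field —
      applied per family before merging (requires ``subs``).
    * ``clustering``: ``k_min``/``k_max``/``min_group_size`` — used only
      when no annotation is supplied.
    * ``scan``: any :class:`ScanConfig` field, including ``seed``.
    * ``reference``: mapping family -> ``{seq_id, start_number}``.

    Fails before any computation if a referenced input is missing; writes
    ``merged.fasta`` (if merging), ``families.tsv`` (if clustering),
    ``positions.tsv``, ``family_table.tsv`` and ``provenance.yaml`` into
    ``out_dir``.
    """
    inputs = config.get("inputs", {})
    out_dir = Path(out_dir)

    # Fail-fast validation of every referenced file.
    have_alignment = "alignment" in inputs
    have_merge = "core" in inputs and "subs" in inputs
    if not have_alignment and not have_merge:
        raise AlignmentError(
            "config must provide inputs.alignment or inputs.core + inputs.subs"
        )
    if have_alignment:
        _require_file(inputs["alignment"], "alignment")
    if have_merge:
        _require_file(inputs["core"], "core alignment")
        for fam, p in inputs["subs"].items():
            _require_file(p, f"sub-alignment for {fam}")
        if "representatives" not in inputs:
            raise AlignmentError("merge inputs require inputs.representatives")
    if "families" in inputs:
        _require_file(inputs["families"], "family annotation")

    filter_cfg_dict = dict(config.get("filters", {}))
    filters_enabled = filter_cfg_dict.pop("enabled", False)
    filter_cfg = FilterConfig(**filter_cfg_dict) if filters_enabled else None
    scan_cfg = ScanConfig(**config.get("scan", {}))
    out_dir.mkdir(parents=True, exist_ok=True)

    annotation: FamilyAnnotation | None = None
    if have_merge:
        core = read_alignment(inputs["core"])
        reps = inputs["representatives"]
        subs: dict[str, MultipleAlignment] = {}
        for fam, p in inputs["subs"].items():
            sub = read_alignment(p)
            if filter_cfg is not None:
                sub, _reports = clean_family(sub, reps[fam], filter_cfg)
                _log(f"filtered family {fam}: {sub.n_sequences} retained", quiet)
            subs[fam] = sub
        fixture = MergeFixture(core=core, subs=subs, representative_of=dict(reps))
        merged = merge_by_core(fixture)
        alignment = merged.alignment
        write_alignment(alignment, out_dir / "merged.fasta")
        write_provenance(merged.provenance, out_dir / "merge_columns.tsv")
        annotation = FamilyAnnotation(
            {
                sid: fam
                for fam, sub in subs.items()
                for sid in sub.ids
            }
        )
        _log(f"merged alignment: {alignment.n_sequences} x {alignment.n_columns}", quiet)
    else:
        alignment = read_alignment(inputs["alignment"])

    if "families" in inputs:
        annotation = read_family_annotation(inputs["families"], alignment)
    clustering_used = False
    if annotation is None:
        c = config.get("clustering", {})
        result = cluster_specificity_groups(
            alignment,
            range(int(c.get("k_min", 2)), int(c.get("k_max", 10)) + 1),
            min_group_size=int(c.get("min_group_size", 2)),
        )
        annotation = result.annotation
        clustering_used = True
        write_family_annotation(annotation, out_dir / "families.tsv")
        _log(f"clustered into k={result.k} specificity groups", quiet)

    numberings: dict[str, ReferenceNumbering] = {}
    for fam, spec in config.get("reference", {}).items():
        numberings[fam] = ReferenceNumbering(
            seq_id=spec["seq_id"], start_number=int(spec.get("start_number", 1))
        )

    classifications = classify_positions(
        alignment, annotation, numberings or None, scan_cfg
    )
    write_positions_tsv(
        classifications, annotation.families, out_dir / "positions.tsv"
    )

    if numberings and all(f in numberings for f in annotation.families):
        table = build_family_table(
            classifications, alignment, annotation, numberings
        )
    else:
        table = pd.DataFrame(index=pd.Index(annotation.families, name="family"))
    table.to_csv(out_dir / "family_table.tsv", sep="\t")

    provenance = {
        "software": {"name": "fspscan", "version": _package_version()},
        "statistic": STATISTIC_NAME,
        "clustering_objective": OBJECTIVE_NAME if clustering_used else None,
        "config": config,
        "seed": scan_cfg.seed,
    }
    with open(out_dir / "provenance.yaml", "w") as fh:
        yaml.safe_dump(provenance, fh, sort_keys=True)
    return ScanResultBundle(
        classifications=classifications,
        family_table=table,
        provenance=provenance,
    )
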