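"""Curation of candidate marker sequences to minimize false positives.

Occupancy models assume no false positives, so every candidate protein
annotated with a marker's KO must be screened before it can count as a
detection.  Three stages compose:

1. a per-marker length window derived from the true-positive references
   (shortest reference minus 50 residues to longest plus 50), dropping
   partial and fused sequences;
2. top-hit classification against a labeled homology-search database — a
   candidate survives only if its best-scoring hit is a labeled true
   positive (off-target homologs such as the ammonia monooxygenases, or
   ANME-type MCR, are labeled false positives);
3. an optional tree screen replacing manual phylogenetic judgment with an
   explicit heuristic: a candidate is flagged when its nearest labeled
   leaf by patristic distance is a false positive, or when its terminal
   branch exceeds median + c * MAD of all terminal branches.

Each stage records a per-sequence disposition so the report partitions the
input exactly.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from Bio import SeqIO

from .panels import MarkerPanel

LENGTH_MARGIN = 50  # residues added/subtracted around the reference lengths
DEFAULT_BRANCH_C = 6.0  # long-branch threshold: median + c * MAD

TRUE_POSITIVE = "true_positive"
FALSE_POSITIVE = "false_positive"

#: Disposition reason codes, in pipeline order.
REASONS = ("too_short", "too_long", "fp_top_hit", "no_hit", "nearest_fp", "long_branch", "kept")

HIT_COLUMNS = (
    "qseqid sseqid pident length mismatch gapopen qstart qend sstart send evalue bitscore"
).split()


class CurationConfigError(ValueError):
    """Raised when reference/label inputs cannot support a curation stage."""


@dataclass
class ReferenceSet:
    """Labeled reference proteins, one table for all markers.

    Columns: ``seq_id, marker, label, organism, length, sequence`` with
    labels in {true_positive, false_positive}.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"seq_id", "marker", "label", "length"}
        if not required.issubset(self.table.columns):
            raise ValueError(f"reference table needs columns {sorted(required)}")
        bad = set(self.table["label"]) - {TRUE_POSITIVE, FALSE_POSITIVE}
        if bad:
            raise ValueError(f"labels must be binary true_positive/false_positive, got {sorted(bad)}")
        if (self.table["length"] <= 0).any():
            raise ValueError("reference lengths must be positive")

    @classmethod
    def from_files(cls, fasta_path, label_path, sep: str = "\t") -> "ReferenceSet":
        labels = pd.read_csv(label_path, sep=sep)
        if not {"subject_id", "label"}.issubset(labels.columns):
            labels = pd.read_csv(label_path, sep=sep, names=["subject_id", "label", "marker"])
        label_map = dict(zip(labels["subject_id"], labels["label"]))
        marker_map = (
            dict(zip(labels["subject_id"], labels["marker"])) if "marker" in labels.columns else {}
        )
        rows = []
        for rec in SeqIO.parse(str(fasta_path), "fasta"):
            rows.append(
                {
                    "seq_id": rec.id,
                    "marker": marker_map.get(rec.id, ""),
                    "label": label_map.get(rec.id, FALSE_POSITIVE),
                    "organism": rec.description.partition(" ")[2],
                    "length": len(rec.seq),
                    "sequence": str(rec.seq),
                }
            )
        return cls(pd.DataFrame(rows))

    def labels(self) -> dict[str, str]:
        return dict(zip(self.table["seq_id"], self.table["label"]))

    def true_positive_lengths(self, marker: str) -> np.ndarray:
        sub = self.table[(self.table["marker"] == marker) & (self.table["label"] == TRUE_POSITIVE)]
        return sub["length"].to_numpy()


def length_window(refs: ReferenceSet, marker: str) -> tuple[int, int]:
    """Per-marker length window from true-positive references only.

    (min reference length - 50, max + 50), with the minimum floored at 1.
    False-positive references describe what to exclude, not the target
    family, so they do not shape the window.
    """
    lengths = refs.true_positive_lengths(marker)
    if lengths.size == 0:
        raise CurationConfigError(f"no true-positive references for marker {marker!r}")
    lo = max(1, int(lengths.min()) - LENGTH_MARGIN)
    hi = int(lengths.max()) + LENGTH_MARGIN
    return lo, hi


def parse_candidates(fasta_path, delimiter: str = "|") -> pd.DataFrame:
    """Candidate FASTA with ids ``metagenomeID<delim>marker<delim>localID``."""
    rows = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        parts = rec.id.split(delimiter)
        if len(parts) < 3:
            raise ValueError(
                f"candidate id {rec.id!r} does not follow metagenomeID{delimiter}marker{delimiter}localID"
            )
        if not parts[0]:
            raise ValueError(f"empty metagenome id in candidate {rec.id!r}")
        rows.append(
            {
                "seq_id": rec.id,
                "metagenome_id": parts[0],
                "marker": parts[1],
                "length": len(rec.seq),
                "sequence": str(rec.seq),
            }
        )
    return pd.DataFrame(rows, columns=["seq_id", "metagenome_id", "marker", "length", "sequence"])


def filter_by_length(cands: pd.DataFrame, window: tuple[int, int]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition candidates by the inclusive length window.

    Returns (kept, removed); removed rows carry a ``reason`` column of
    too_short / too_long.
    """
    lo, hi = window
    lengths = cands["length"]
    keep = (lengths >= lo) & (lengths <= hi)
    removed = cands.loc[~keep].copy()
    removed["reason"] = np.where(removed["length"] < lo, "too_short", "too_long")
    return cands.loc[keep].copy(), removed


def read_hits(path_or_buffer, sep: str = "\t") -> pd.DataFrame:
    """Read 12-column tabular homology-search output (blast/diamond outfmt 6)."""
    if isinstance(path_or_buffer, str) and "\n" in path_or_buffer:
        path_or_buffer = io.StringIO(path_or_buffer)
    df = pd.read_csv(path_or_buffer, sep=sep, names=HIT_COLUMNS, header=None, dtype=str)
    if df.shape[1] != len(HIT_COLUMNS):
        raise ValueError(f"expected {len(HIT_COLUMNS)} columns, found {df.shape[1]}")
    for col in ("bitscore", "evalue", "pident"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() | ~np.isfinite(vals)
        if bad.any():
            line = int(np.flatnonzero(bad)[0]) + 1
            raise ValueError(f"malformed hit row at line {line}: non-numeric {col}")
        df[col] = vals
    return df


def classify_by_top_hit(
    hits: pd.DataFrame,
    labels: dict[str, str],
    queries: list[str] | None = None,
) -> tuple[list[str], pd.DataFrame]:
    """Keep queries whose best-scoring subject is a labeled true positive.

    The top hit is the maximum bit score.  On exact ties, the query is
    kept only if every tied-best subject is a true positive — the
    conservative reading of a no-false-positives requirement.  Queries
    listed in ``queries`` but absent from the hit table are removed with
    reason ``no_hit``: absence of homology evidence cannot certify a true
    positive.  The result is invariant to the row order of ``hits``.
    """
    kept: list[str] = []
    removed_rows: list[dict] = []
    seen = set()
    if len(hits):
        for qid, grp in hits.groupby("qseqid", sort=True):
            seen.add(qid)
            best = grp.loc[grp["bitscore"] == grp["bitscore"].max()]
            subjects = sorted(set(best["sseqid"]))
            if all(labels.get(s) == TRUE_POSITIVE for s in subjects):
                kept.append(qid)
            else:
                removed_rows.append({"seq_id": qid, "reason": "fp_top_hit"})
    if queries is not None:
        for qid in queries:
            if qid not in seen:
                removed_rows.append({"seq_id": qid, "reason": "no_hit"})
        kept = [q for q in kept if q in set(queries)]
    removed = pd.DataFrame(removed_rows, columns=["seq_id", "reason"])
    return kept, removed


def _load_tree(tree) -> dendropy.Tree:
    if isinstance(tree, dendropy.Tree):
        return tree
    if isinstance(tree, str) and tree.lstrip().startswith("("):
        return dendropy.Tree.get(data=tree, schema="newick", preserve_underscores=True)
    return dendropy.Tree.get(path=str(tree), schema="newick", preserve_underscores=True)


def tree_screen(
    tree,
    queries: list[str],
    labels: dict[str, str],
    c: float = DEFAULT_BRANCH_C,
) -> tuple[list[str], pd.DataFrame]:
    """Flag queries by nearest labeled leaf and long terminal branches.

    A query is flagged when (a) its nearest labeled reference leaf by
    patristic distance carries a false-positive label, or (b) its terminal
    branch length exceeds median + ``c`` * MAD over all terminal branches
    in the tree.  Raising ``c`` can only grow the kept set.
    """
    t = _load_tree(tree)
    leaf_by_label = {lf.taxon.label: lf for lf in t.leaf_node_iter() if lf.taxon is not None}
    missing = [q for q in queries if q not in leaf_by_label]
    if missing:
        raise ValueError(f"query leaf (leaves) absent from tree: {missing}")
    ref_ids = [r for r in labels if r in leaf_by_label]
    if not any(labels[r] == TRUE_POSITIVE for r in ref_ids):
        raise CurationConfigError("tree contains no true-positive reference leaf")

    pdm = t.phylogenetic_distance_matrix()
    taxa = {lf.taxon.label: lf.taxon for lf in t.leaf_node_iter()}
    terminal = np.array(
        [lf.edge.length or 0.0 for lf in t.leaf_node_iter()], dtype=float
    )
    med = float(np.median(terminal))
    mad = float(np.median(np.abs(terminal - med)))
    threshold = med + c * mad

    kept: list[str] = []
    flagged_rows: list[dict] = []
    for q in queries:
        qleaf = leaf_by_label[q]
        dists = {
            r: pdm.patristic_distance(taxa[q], taxa[r]) for r in ref_ids if r != q
        }
        nearest = min(sorted(dists), key=lambda r: (dists[r], r))
        if labels[nearest] == FALSE_POSITIVE:
            flagged_rows.append({"seq_id": q, "reason": "nearest_fp"})
        elif (qleaf.edge.length or 0.0) > threshold:
            flagged_rows.append({"seq_id": q, "reason": "long_branch"})
        else:
            kept.append(q)
    flagged = pd.DataFrame(flagged_rows, columns=["seq_id", "reason"])
    return kept, flagged


@dataclass
class CurationReport:
    """Stage-count bookkeeping plus per-sequence dispositions."""

    counts: dict[str, int]
    dispositions: pd.DataFrame  # columns: seq_id, metagenome_id, marker, status, reason
    tree_stage_run: bool = True
    parameters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        stages = ["initial", "after_length", "after_top_hit", "after_tree"]
        vals = [self.counts[s] for s in stages if s in self.counts]
        if any(a < b for a, b in zip(vals, vals[1:])):
            raise ValueError(f"stage counts must be non-increasing: {self.counts}")
        if len(self.dispositions) != self.counts.get("initial", len(self.dispositions)):
            raise ValueError("dispositions must partition the input")

    def to_log(self) -> str:
        lines = ["curation report"]
        for stage, n in self.counts.items():
            lines.append(f"  {stage}: {n}")
        if not self.tree_stage_run:
            lines.append("  (tree screen skipped: no tree supplied)")
        for reason, n in self.dispositions["reason"].value_counts().items():
            lines.append(f"  reason {reason}: {n}")
        return "\n".join(lines)


@dataclass
class CurationResult:
    evidence: pd.DataFrame  # metagenome_id, marker, n_sequences
    report: CurationReport
    kept_ids: list[str]


def curate(
    panel: MarkerPanel,
    refs: ReferenceSet,
    cands: pd.DataFrame,
    hits: pd.DataFrame,
    tree=None,
    c: float = DEFAULT_BRANCH_C,
) -> CurationResult:
    """Run length -> top-hit -> tree screening and tally evidence.

    ``tree`` may be None (stage skipped, recorded in the report), a single
    tree applied to all markers, or a mapping marker -> tree.  The evidence
    table counts surviving sequences per metagenome and marker; detection
    histories threshold these counts at >= 1.
    """
    unknown = set(cands["marker"]) - set(panel.markers)
    if unknown:
        raise ValueError(f"candidates carry marker(s) {sorted(unknown)} not in panel {panel.function_name!r}")

    disposition: dict[str, str] = {}
    labels = refs.labels()

    kept_frames = []
    n_after_length = 0
    n_after_tophit = 0
    n_after_tree = 0
    for marker in panel.markers:
        sub = cands[cands["marker"] == marker]
        if sub.empty:
            continue
        window = length_window(refs, marker)
        kept_len, removed_len = filter_by_length(sub, window)
        for _, row in removed_len.iterrows():
            disposition[row["seq_id"]] = row["reason"]
        n_after_length += len(kept_len)

        kept_ids, removed_hits = classify_by_top_hit(hits, labels, queries=list(kept_len["seq_id"]))
        for _, row in removed_hits.iterrows():
            disposition[row["seq_id"]] = row["reason"]
        n_after_tophit += len(kept_ids)

        if tree is not None:
            marker_tree = tree.get(marker) if isinstance(tree, dict) else tree
        else:
            marker_tree = None
        if marker_tree is not None and kept_ids:
            kept_ids, flagged = tree_screen(marker_tree, kept_ids, labels, c=c)
            for _, row in flagged.iterrows():
                disposition[row["seq_id"]] = row["reason"]
        n_after_tree += len(kept_ids)
        for q in kept_ids:
            disposition[q] = "kept"
        kept_frames.append(kept_len[kept_len["seq_id"].isin(set(kept_ids))])

    kept_all = (
        pd.concat(kept_frames, ignore_index=True)
        if kept_frames
        else cands.iloc[0:0].copy()
    )
    evidence = (
        kept_all.groupby(["metagenome_id", "marker"], sort=True)
        .size()
        .rename("n_sequences")
        .reset_index()
        if len(kept_all)
        else pd.DataFrame(columns=["metagenome_id", "marker", "n_sequences"])
    )

    disp_df = cands[["seq_id", "metagenome_id", "marker"]].copy()
    disp_df["reason"] = [disposition.get(s, "kept") for s in disp_df["seq_id"]]
    disp_df["status"] = np.where(disp_df["reason"] == "kept", "kept", "removed")

    report = CurationReport(
        counts={
            "initial": len(cands),
            "after_length": n_after_length,
            "after_top_hit": n_after_tophit,
            "after_tree": n_after_tree,
        },
        dispositions=disp_df,
        tree_stage_run=tree is not None,
        parameters={"branch_c": c, "length_margin": LENGTH_MARGIN},
    )
    return CurationResult(evidence=evidence, report=report, kept_ids=sorted(disposition_kept(disp_df)))


def disposition_kept(disp_df: pd.DataFrame) -> list[str]:
    return list(disp_df.loc[disp_df["status"] == "kept", "seq_id"])
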