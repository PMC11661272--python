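"""Similarity-aware dataset curation for residue-level pKa records.

Data leakage is the central risk when training and evaluating on
experimental pKa values: the same residue in two homologous structures is
effectively one data point.  Two records x and y are *similar* when all
three of the following hold:

* **P** — their parent sequences fall in the same cluster with pairwise
  identity > 0.5,
* **A** — the residues occupy the same column of the cluster's multiple
  alignment,
* **T** — the residues are of the same amino-acid type,

and a leakage-proof split guarantees ¬(P ∧ A ∧ T) for every (train, test)
and (train, validation) pair, with within-set deduplication of the
validation and test sets.

Clustering is greedy and length-sorted (each sequence joins the first
representative with identity above the threshold), with identity defined
as matches over the global-alignment length (gap-inclusive denominator).
Multiple alignments use a center-star progressive scheme built on
Biopython's pairwise aligner.  Adapters ingest externally produced CD-HIT
``.clstr`` and aligned-FASTA files for exact reproduction of external
pipelines.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import Align

__all__ = [
    "PkaRecord",
    "ClusterAlignment",
    "Clustering",
    "pairwise_identity",
    "cluster_sequences",
    "align_cluster",
    "similar",
    "split_dataset",
    "SplitResult",
    "read_clstr",
    "read_aligned_fasta",
    "write_fasta",
]


@dataclass(frozen=True)
class PkaRecord:
    """One ionizable-residue data point with provenance for splitting."""

    structure_id: str
    chain: str
    residue_number: int     # 1-based position in the parent sequence
    residue_type: str
    pka_exp: float

    @property
    def label(self) -> str:
        return f"{self.structure_id}_{self.chain}:{self.residue_number}:{self.residue_type}"


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 2.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -5.0
    aligner.extend_gap_score = -1.0
    return aligner


_ALIGNER = _make_aligner()


def _alignment_blocks(seq_a: str, seq_b: str):
    aln = _ALIGNER.align(seq_a, seq_b)[0]
    return aln.aligned


def pairwise_identity(seq_a: str, seq_b: str) -> float:
    """Matches over global-alignment length (gap-inclusive denominator)."""
    if not seq_a or not seq_b:
        raise ValueError("empty sequence")
    blocks_a, blocks_b = _alignment_blocks(seq_a, seq_b)
    matches = 0
    paired = 0
    for (a0, a1), (b0, b1) in zip(blocks_a, blocks_b):
        paired += a1 - a0
        matches += sum(seq_a[a0 + k] == seq_b[b0 + k] for k in range(a1 - a0))
    columns = len(seq_a) + len(seq_b) - paired
    return matches / columns


@dataclass
class ClusterAlignment:
    """Residue-position -> alignment-column maps for one cluster."""

    members: list[str]
    column_of: dict[str, np.ndarray]  # seq_id -> (len(seq),) int columns
    n_columns: int

    def column(self, seq_id: str, position: int) -> int:
        """Alignment column of 1-based sequence position ``position``."""
        cols = self.column_of[seq_id]
        if not 1 <= position <= len(cols):
            raise IndexError(f"position {position} outside sequence {seq_id}")
        return int(cols[position - 1])


def align_cluster(sequences: dict[str, str]) -> ClusterAlignment:
    """Center-star multiple alignment (center = longest member).

    Every other member is globally aligned to the center; gap columns are
    merged so the final position->column maps are injective and strictly
    monotone per sequence.  Insertions relative to the center occupy
    dedicated columns (right-aligned within their gap region).
    """
    members = list(sequences)
    if len(members) == 1:
        sid = members[0]
        n = len(sequences[sid])
        return ClusterAlignment(members, {sid: np.arange(n)}, n)

    center = max(members, key=lambda s: (len(sequences[s]), s))
    cseq = sequences[center]
    nc = len(cseq)
    # per sequence: center index per position (-1 for insertions)
    maps: dict[str, np.ndarray] = {center: np.arange(nc)}
    for sid in members:
        if sid == center:
            continue
        seq = sequences[sid]
        m = np.full(len(seq), -1, dtype=int)
        blocks_c, blocks_s = _alignment_blocks(cseq, seq)
        for (c0, c1), (s0, s1) in zip(blocks_c, blocks_s):
            m[s0:s1] = np.arange(c0, c1)
        maps[sid] = m

    # width of the insertion region before each center position (and trailing)
    ins_before = np.zeros(nc + 1, dtype=int)
    runs: dict[str, list[tuple[int, int, int]]] = {}  # sid -> (start_pos, length, anchor)
    for sid, m in maps.items():
        seq_runs = []
        i = 0
        while i < len(m):
            if m[i] == -1:
                j = i
                while j < len(m) and m[j] == -1:
                    j += 1
                anchor = int(m[j]) if j < len(m) else nc
                seq_runs.append((i, j - i, anchor))
                ins_before[anchor] = max(ins_before[anchor], j - i)
                i = j
            else:
                i += 1
        runs[sid] = seq_runs

    gap_start = np.zeros(nc + 1, dtype=int)
    acc = 0
    for i in range(nc + 1):
        gap_start[i] = acc
        acc += int(ins_before[i]) + 1
    n_columns = acc - 1  # no column for the virtual center position nc
    col_center = gap_start[:nc] + ins_before[:nc]

    column_of: dict[str, np.ndarray] = {}
    for sid, m in maps.items():
        cols = np.empty(len(m), dtype=int)
        aligned = m >= 0
        cols[aligned] = col_center[m[aligned]]
        for start, length, anchor in runs[sid]:
            region_end = gap_start[anchor] + ins_before[anchor]
            if anchor == nc:
                region_end = n_columns
            cols[start : start + length] = np.arange(region_end - length, region_end)
        column_of[sid] = cols
    return ClusterAlignment(members, column_of, n_columns)


@dataclass
class Clustering:
    """Greedy identity clustering plus per-cluster alignments."""

    threshold: float
    clusters: list[list[str]]
    cluster_of: dict[str, int]
    alignments: list[ClusterAlignment]
    sequences: dict[str, str] = field(repr=False, default_factory=dict)
    _identity_cache: dict[tuple[str, str], float] = field(default_factory=dict, repr=False)

    def identity(self, a: str, b: str) -> float:
        key = (a, b) if a <= b else (b, a)
        if key not in self._identity_cache:
            self._identity_cache[key] = pairwise_identity(self.sequences[a], self.sequences[b])
        return self._identity_cache[key]


def cluster_sequences(sequences: dict[str, str], threshold: float = 0.5) -> Clustering:
    """Greedy length-sorted clustering at a sequence-identity threshold.

    Sequences are visited longest-first; each joins the first existing
    cluster whose representative (its founding, longest member) has
    identity strictly greater than the threshold, else founds a cluster.
    """
    for sid, seq in sequences.items():
        if not seq:
            raise ValueError(f"empty sequence: {sid!r}")
    order = sorted(sequences, key=lambda s: (-len(sequences[s]), s))
    reps: list[str] = []
    clusters: list[list[str]] = []
    cache: dict[tuple[str, str], float] = {}
    for sid in order:
        for ci, rep in enumerate(reps):
            ident = pairwise_identity(sequences[rep], sequences[sid])
            key = (rep, sid) if rep <= sid else (sid, rep)
            cache[key] = ident
            if ident > threshold:
                clusters[ci].append(sid)
                break
        else:
            reps.append(sid)
            clusters.append([sid])
    cluster_of = {sid: ci for ci, members in enumerate(clusters) for sid in members}
    alignments = [align_cluster({sid: sequences[sid] for sid in members}) for members in clusters]
    return Clustering(
        threshold=threshold,
        clusters=clusters,
        cluster_of=cluster_of,
        alignments=alignments,
        sequences=dict(sequences),
        _identity_cache=cache,
    )


def _record_fields(record) -> tuple[str, int, str]:
    if isinstance(record, PkaRecord):
        return record.structure_id, record.residue_number, record.residue_type
    return (
        str(record["structure_id"]),
        int(record["residue_number"]),
        str(record["residue_type"]),
    )


def similar(x, y, clustering: Clustering) -> bool:
    """P(x, y) ∧ A(x, y) ∧ T(x, y); symmetric and reflexive."""
    sid_x, pos_x, type_x = _record_fields(x)
    sid_y, pos_y, type_y = _record_fields(y)
    for sid in (sid_x, sid_y):
        if sid not in clustering.cluster_of:
            raise KeyError(f"sequence {sid!r} absent from clustering")
    if type_x != type_y:  # T
        return False
    ci = clustering.cluster_of[sid_x]
    if ci != clustering.cluster_of[sid_y]:  # P (cluster part)
        return False
    if sid_x != sid_y and clustering.identity(sid_x, sid_y) <= clustering.threshold:
        return False  # P (identity part)
    aln = clustering.alignments[ci]
    return aln.column(sid_x, pos_x) == aln.column(sid_y, pos_y)  # A


@dataclass
class SplitResult:
    train: pd.DataFrame
    validation: pd.DataFrame
    test: pd.DataFrame
    removed: pd.DataFrame
    clustering: Clustering = field(repr=False)

    def audit(self) -> pd.DataFrame:
        """Brute-force all-pairs leakage check; empty frame = clean split."""
        violations = []
        for other_name, other in (("validation", self.validation), ("test", self.test)):
            for _, x in self.train.iterrows():
                for _, y in other.iterrows():
                    if similar(x, y, self.clustering):
                        violations.append(
                            {
                                "train_record": _label(x),
                                "set": other_name,
                                "other_record": _label(y),
                            }
                        )
        return pd.DataFrame(violations, columns=["train_record", "set", "other_record"])


def _label(row) -> str:
    return f"{row['structure_id']}:{row['residue_number']}:{row['residue_type']}"


def split_dataset(
    records: pd.DataFrame,
    sequences: dict[str, str],
    ratios: tuple[float, float, float] = (0.8, 0.1, 0.1),
    seed: int = 0,
    threshold: float = 0.5,
    clustering: Clustering | None = None,
) -> SplitResult:
    """Random split with within-set dedup and train-leakage removal.

    Validation and test sets are deduplicated internally (the first record
    in input order wins among mutually similar ones), then purged of any
    record similar to a training record.  The returned audit report lists
    every removal with its reason; re-running with the same seed
    reproduces the split exactly.
    """
    if clustering is None:
        clustering = cluster_sequences(sequences, threshold)
    rng = np.random.default_rng(seed)
    records = records.reset_index(drop=True)
    order = rng.permutation(len(records))
    n = len(records)
    n_train = int(round(ratios[0] * n))
    n_val = int(round(ratios[1] * n))
    train_idx = set(order[:n_train])
    val_idx = set(order[n_train : n_train + n_val])
    test_idx = set(order[n_train + n_val :])

    train = records.iloc[sorted(train_idx)]
    removed_rows = []

    def dedup_and_purge(idx_set, set_name):
        kept = []
        for i in sorted(idx_set):  # input order; first record wins
            row = records.iloc[i]
            dup = next((j for j in kept if similar(records.iloc[j], row, clustering)), None)
            if dup is not None:
                removed_rows.append(
                    {"record": _label(row), "set": set_name,
                     "reason": f"similar to {_label(records.iloc[dup])} in {set_name}"}
                )
                continue
            leak = next(
                (j for j in train.index if similar(records.iloc[j], row, clustering)), None
            )
            if leak is not None:
                removed_rows.append(
                    {"record": _label(row), "set": set_name,
                     "reason": f"similar to training record {_label(records.iloc[leak])}"}
                )
                continue
            kept.append(i)
        return records.iloc[kept]

    validation = dedup_and_purge(val_idx, "validation")
    test = dedup_and_purge(test_idx, "test")
    removed = pd.DataFrame(removed_rows, columns=["record", "set", "reason"])
    return SplitResult(train=train, validation=validation, test=test,
                       removed=removed, clustering=clustering)


# ---------------------------------------------------------------------------
# Adapters and FASTA output


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    lines = []
    for sid, seq in sequences.items():
        lines.append(f">{sid}")
        lines.extend(seq[i : i + 70] for i in range(0, len(seq), 70))
    Path(path).write_text("\n".join(lines) + "\n")


def read_clstr(path: str | Path) -> list[list[str]]:
    """Parse CD-HIT ``.clstr`` output into clusters of sequence ids."""
    clusters: list[list[str]] = []
    for line in Path(path).read_text().splitlines():
        if line.startswith(">Cluster"):
            clusters.append([])
        elif line.strip():
            sid = line.split(">", 1)[1].split("...", 1)[0]
            clusters[-1].append(sid)
    return clusters


def read_aligned_fasta(path: str | Path) -> ClusterAlignment:
    """Build position->column maps from an externally aligned FASTA file."""
    seqs: dict[str, str] = {}
    sid = None
    for line in Path(path).read_text().splitlines():
        if line.startswith(">"):
            sid = line[1:].split()[0]
            seqs[sid] = ""
        elif sid is not None:
            seqs[sid] += line.strip()
    lengths = {len(s) for s in seqs.values()}
    if len(lengths) != 1:
        raise ValueError("aligned FASTA rows have unequal lengths")
    column_of = {}
    for sid, aligned in seqs.items():
        cols = [i for i, c in enumerate(aligned) if c not in "-."]
        column_of[sid] = np.array(cols, dtype=int)
    return ClusterAlignment(list(seqs), column_of, lengths.pop())
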