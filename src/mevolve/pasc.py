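"""All-vs-all pairwise sequence identity histograms.

Given a collection of nucleotide sequences, every unordered pair is scored
for percent identity and the identities are binned into a frequency
histogram. For sets of related viral genomes such histograms show a series
of peaks — each peak a cloud of pairs at a characteristic divergence — and
the valleys between peaks mark natural demarcation thresholds between
taxonomic levels (strain, species, genus). With a sequence-to-group map the
histogram separates within-group from between-group comparisons.

Two identity methods are provided, since real pipelines differ on this
point: ``aligned_columns`` compares equal-length sequences column by
column, and ``global_align`` first computes a standard global alignment
(Biopython's PairwiseAligner, EMBOSS-like scoring) and scores identity over
aligned columns excluding terminal gaps.

A fixture generator emits synthetic FASTA with a designed cluster
structure, so multi-peak histograms can be produced and verified offline.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Align import PairwiseAligner
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "pairwise_identity",
    "build_histogram",
    "IdentityHistogram",
    "generate_fixture_fasta",
    "group_map_from_records",
    "read_group_map",
]

_BASES = "ACGT"


def _aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 5.0
    aligner.mismatch_score = -4.0
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    return aligner


def pairwise_identity(a: str, b: str, method: str = "aligned_columns") -> float:
    """Percent identity of two nucleotide sequences, in [0, 100].

    ``aligned_columns`` treats the sequences as already aligned and requires
    equal lengths; identity is 100 x matches / length. ``global_align``
    aligns globally first and scores identity over aligned columns with
    terminal gap columns excluded (internal gap columns count as compared
    mismatches).
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    a, b = a.upper(), b.upper()
    if method == "aligned_columns":
        if len(a) != len(b):
            raise ValueError(
                f"aligned_columns requires equal lengths ({len(a)} vs {len(b)}); "
                "use method='global_align' for unaligned sequences"
            )
        matches = sum(x == y for x, y in zip(a, b))
        return 100.0 * matches / len(a)
    if method == "global_align":
        alignment = _aligner().align(a, b)[0]
        row_a, row_b = str(alignment[0]), str(alignment[1])
        start = max(len(row_a) - len(row_a.lstrip("-")), len(row_b) - len(row_b.lstrip("-")))
        end = min(len(row_a.rstrip("-")), len(row_b.rstrip("-")))
        if end <= start:
            return 0.0
        matches = 0
        for x, y in zip(row_a[start:end], row_b[start:end]):
            if x == y and x != "-":
                matches += 1
        return 100.0 * matches / (end - start)
    raise ValueError(f"unknown method {method!r}; expected aligned_columns or global_align")


@dataclass(frozen=True)
class IdentityHistogram:
    """Binned all-vs-all identity frequencies with peak/valley annotations.

    Bins are half-open ``[lo, hi)`` with the last bin closed. ``counts``
    is indexed by bin with columns within_group / between_group / ungrouped;
    ``pairs`` lists every unordered pair with its identity and class.
    ``peaks`` and ``valleys`` are bin indices of local maxima of the
    (lightly smoothed) total counts and of the minima between consecutive
    peaks.
    """

    bin_edges: np.ndarray
    counts: pd.DataFrame
    pairs: pd.DataFrame
    peaks: List[int]
    valleys: List[int]
    method: str
    bin_width: float

    @property
    def total_counts(self) -> np.ndarray:
        return self.counts[["within_group", "between_group", "ungrouped"]].sum(axis=1).to_numpy()

    def peak_identities(self) -> List[float]:
        """Bin-midpoint identity of each detected peak."""
        return [
            float((self.bin_edges[i] + self.bin_edges[i + 1]) / 2.0) for i in self.peaks
        ]

    def valley_identities(self) -> List[float]:
        return [
            float((self.bin_edges[i] + self.bin_edges[i + 1]) / 2.0) for i in self.valleys
        ]


def _find_peaks_and_valleys(counts: np.ndarray) -> Tuple[List[int], List[int]]:
    # 3-bin moving average guards against single-bin jitter splitting a peak
    kernel = np.ones(3) / 3.0
    smooth = np.convolve(counts.astype(float), kernel, mode="same")
    peaks: List[int] = []
    n = len(smooth)
    for i in range(n):
        if smooth[i] <= 0:
            continue
        left = smooth[i - 1] if i > 0 else -np.inf
        right = smooth[i + 1] if i < n - 1 else -np.inf
        if smooth[i] > left and smooth[i] >= right:
            peaks.append(i)
    valleys: List[int] = []
    for a, b in zip(peaks, peaks[1:]):
        valleys.append(int(a + 1 + np.argmin(smooth[a + 1 : b])))
    return peaks, valleys


RecordsLike = Union[str, Path, Iterable]


def _load_records(records: RecordsLike) -> List[SeqRecord]:
    if isinstance(records, (str, Path)):
        return list(SeqIO.parse(str(records), "fasta"))
    out = []
    for r in records:
        if isinstance(r, SeqRecord):
            out.append(r)
        else:
            rid, seq = r
            out.append(SeqRecord(Seq(seq), id=rid, description=""))
    return out


def build_histogram(
    records: RecordsLike,
    bin_width: float = 1.0,
    groups: Optional[Mapping[str, str]] = None,
    method: str = "aligned_columns",
) -> IdentityHistogram:
    """All-vs-all percent-identity histogram over a FASTA file or records.

    ``records`` may be a FASTA path, an iterable of Biopython SeqRecords, or
    ``(id, sequence)`` pairs. With a ``groups`` map (sequence id -> group
    label) each pair is classified as within_group, between_group, or — when
    either id is unmapped — ungrouped.
    """
    if not 0 < bin_width <= 100:
        raise ValueError("bin_width must be in (0, 100]")
    recs = _load_records(records)
    if len(recs) < 2:
        raise ValueError("at least 2 sequences are required")

    edges = np.arange(0.0, 100.0 + bin_width, bin_width)
    if edges[-1] < 100.0:
        edges = np.append(edges, 100.0)

    pair_rows = []
    for i in range(len(recs)):
        for j in range(i + 1, len(recs)):
            ra, rb = recs[i], recs[j]
            identity = pairwise_identity(str(ra.seq), str(rb.seq), method=method)
            if groups is None:
                cls = "ungrouped"
            else:
                ga, gb = groups.get(ra.id), groups.get(rb.id)
                if ga is None or gb is None:
                    cls = "ungrouped"
                elif ga == gb:
                    cls = "within_group"
                else:
                    cls = "between_group"
            pair_rows.append(
                dict(seq_a_id=ra.id, seq_b_id=rb.id, identity=identity, comparison_class=cls)
            )
    pairs = pd.DataFrame(pair_rows, columns=["seq_a_id", "seq_b_id", "identity", "comparison_class"])

    counts = pd.DataFrame(
        0,
        index=pd.RangeIndex(len(edges) - 1, name="bin"),
        columns=["within_group", "between_group", "ungrouped"],
    )
    for cls in counts.columns:
        vals = pairs.loc[pairs["comparison_class"] == cls, "identity"].to_numpy()
        hist, _ = np.histogram(vals, bins=edges)
        counts[cls] = hist

    total = counts.sum(axis=1).to_numpy()
    peaks, valleys = _find_peaks_and_valleys(total)
    return IdentityHistogram(
        bin_edges=edges,
        counts=counts,
        pairs=pairs,
        peaks=peaks,
        valleys=valleys,
        method=method,
        bin_width=bin_width,
    )


def _mutate_sequence(seq: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Substitute each site with prob ``rate`` by one of the 3 other bases."""
    out = seq.copy()
    hit = rng.random(seq.size) < rate
    n_hit = int(hit.sum())
    if n_hit:
        # shift by 1..3 in base space => always a different base
        out[hit] = (out[hit] + rng.integers(1, 4, size=n_hit)) % 4
    return out


def generate_fixture_fasta(
    n_clusters: int = 2,
    seqs_per_cluster: int = 10,
    length: int = 1000,
    within_divergence: float = 0.02,
    between_divergence: float = 0.20,
    rng_seed: Optional[int] = None,
) -> List[SeqRecord]:
    """Synthetic FASTA with a designed cluster structure.

    Cluster ancestors diverge from a common root at ``between_divergence``
    per site (cluster 1's ancestor is the root itself); members diverge from
    their cluster ancestor at ``within_divergence`` per site. Substitutions
    replace a base with one of the three other bases, so per-lineage
    divergence equals the nominal rate. Record ids are
    ``cluster{c}_seq{s}``; the cluster label is also stored in the record
    description, and :func:`group_map_from_records` recovers the id->cluster map.
    """
    if n_clusters < 1 or seqs_per_cluster < 1 or length < 1:
        raise ValueError("n_clusters, seqs_per_cluster and length must be positive")
    if not (0.0 <= within_divergence <= 1.0 and 0.0 <= between_divergence <= 1.0):
        raise ValueError("divergences must lie in [0, 1]")
    if within_divergence >= between_divergence:
        raise ValueError("within_divergence must be smaller than between_divergence")

    rng = np.random.default_rng(rng_seed)
    root = rng.integers(0, 4, size=length)
    records = []
    for c in range(1, n_clusters + 1):
        ancestor = root if c == 1 else _mutate_sequence(root, between_divergence, rng)
        for s in range(1, seqs_per_cluster + 1):
            member = _mutate_sequence(ancestor, within_divergence, rng)
            seq = "".join(_BASES[b] for b in member)
            records.append(
                SeqRecord(
                    Seq(seq),
                    id=f"cluster{c}_seq{s}",
                    description=f"group=cluster{c}",
                )
            )
    return records


def group_map_from_records(records: Iterable[SeqRecord]) -> Dict[str, str]:
    """Recover the id -> cluster map from fixture record ids."""
    return {r.id: r.id.rsplit("_", 1)[0] for r in records}


def read_group_map(path: Union[str, Path]) -> Dict[str, str]:
    """Read a two-column TSV mapping sequence id to group label."""
    mapping: Dict[str, str] = {}
    with open(path) as handle:
        for line_no, line in enumerate(handle, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{line_no}: expected 'id<TAB>group', got {line!r}")
            mapping[parts[0]] = parts[1]
    return mapping
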