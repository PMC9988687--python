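"""Probe-to-transcript overlap and cross-platform abundance concordance.

A gene is a collection of transcript isoforms; a platform's probe (or a
qPCR amplicon) quantifies only the isoforms whose *spliced* sequence
contains it.  Probes are placed by exact substring match against spliced
transcript sequences — for the aggregation purpose this is equivalent to a
spliced genome alignment, and junction-spanning amplicons match the spliced
sequence naturally.  Per-sample abundance of the probe's transcript
collection is the sum of TPM over matched isoforms in a consistent strand
orientation; two platforms' probes for the same gene are then compared by
the R² of a simple linear regression of one aggregate on the other.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from scipy import stats

__all__ = [
    "TranscriptModel",
    "ProbeMatch",
    "match_probe",
    "aggregate_probe_tpm",
    "platform_concordance",
    "read_transcripts_fasta",
    "read_transcript_exons_gtf",
    "read_tpm",
]

_ALPHABET = set("ACGTN")


@dataclass
class TranscriptModel:
    """A spliced transcript: identity, strand, optional exon structure.

    Exon intervals are 1-based closed (GTF convention), ordered and
    non-overlapping; when both exons and sequence are given the spliced
    sequence length must equal the summed exon lengths.  Genomic
    coordinates are optional metadata — matching uses the spliced sequence
    only.
    """

    transcript_id: str
    gene_id: str
    sequence: str
    strand: str = "+"
    exons: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if set(self.sequence) - _ALPHABET:
            raise ValueError(
                f"transcript {self.transcript_id!r} has non-ACGTN characters")
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.exons:
            for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
                if not (s1 <= e1 < s2 <= e2):
                    raise ValueError(
                        f"exons of {self.transcript_id!r} must be ordered "
                        "and non-overlapping")
            total = sum(e - s + 1 for s, e in self.exons)
            if total != len(self.sequence):
                raise ValueError(
                    f"spliced length {len(self.sequence)} != summed exon "
                    f"length {total} for {self.transcript_id!r}")

    @property
    def is_intronless(self) -> bool:
        return len(self.exons) <= 1


@dataclass
class ProbeMatch:
    """Transcripts whose spliced sequence contains a probe (either strand)."""

    probe_id: str
    platform: str  # "microarray" | "qrt-pcr"
    orientation: dict[str, str]  # transcript id -> "sense" | "antisense"

    @property
    def transcript_ids(self) -> list[str]:
        return list(self.orientation)

    @property
    def majority_orientation(self) -> str | None:
        """Orientation used for aggregation, chosen by majority of matches
        (ties resolve to sense)."""
        if not self.orientation:
            return None
        counts = Counter(self.orientation.values())
        return max(("sense", "antisense"), key=lambda o: counts[o])

    def transcripts_in_majority(self) -> list[str]:
        maj = self.majority_orientation
        return [t for t, o in self.orientation.items() if o == maj]


def match_probe(probe_id: str, probe_seq: str,
                transcripts: list[TranscriptModel],
                platform: str = "microarray",
                max_mismatches: int = 0) -> ProbeMatch:
    """Place a probe (or amplicon) on a set of spliced transcripts.

    A transcript matches in *sense* orientation when its spliced sequence
    contains the probe verbatim, and in *antisense* orientation when it
    contains the probe's reverse complement.  Probes shorter than 15 nt or
    with more than 20% ambiguous bases are rejected.  ``max_mismatches``
    allows Hamming-distance placements (default 0 = exact only).
    """
    probe_seq = probe_seq.upper()
    if len(probe_seq) < 15:
        raise ValueError(f"probe {probe_id!r} shorter than 15 nt")
    if set(probe_seq) - _ALPHABET:
        raise ValueError(f"probe {probe_id!r} has non-ACGTN characters")
    if probe_seq.count("N") / len(probe_seq) > 0.20:
        raise ValueError(f"probe {probe_id!r} has more than 20% N bases")
    rc = str(Seq(probe_seq).reverse_complement())

    orientation: dict[str, str] = {}
    for t in transcripts:
        if _contains(t.sequence, probe_seq, max_mismatches):
            orientation[t.transcript_id] = "sense"
        elif _contains(t.sequence, rc, max_mismatches):
            orientation[t.transcript_id] = "antisense"
    return ProbeMatch(probe_id=probe_id, platform=platform,
                      orientation=orientation)


def _contains(haystack: str, needle: str, max_mismatches: int) -> bool:
    if max_mismatches == 0:
        return needle in haystack
    k = len(needle)
    if k > len(haystack):
        return False
    arr = np.frombuffer(haystack.encode(), dtype=np.uint8)
    pat = np.frombuffer(needle.encode(), dtype=np.uint8)
    windows = np.lib.stride_tricks.sliding_window_view(arr, k)
    return bool((np.sum(windows != pat, axis=1) <= max_mismatches).any())


def aggregate_probe_tpm(match: ProbeMatch, tpm: pd.DataFrame) -> pd.Series:
    """Per-sample summed TPM over the probe's matched transcript collection.

    ``tpm`` is transcript × sample.  Aggregation is restricted to the
    probe's majority orientation; an empty match set yields a zero vector
    with a warning.
    """
    if (tpm.to_numpy() < 0).any():
        raise ValueError("TPM values must be non-negative")
    tids = match.transcripts_in_majority()
    if not tids:
        warnings.warn(f"probe {match.probe_id!r} matched no transcripts; "
                      "aggregate is zero", stacklevel=2)
        return pd.Series(0.0, index=tpm.columns, name=match.probe_id)
    absent = [t for t in tids if t not in tpm.index]
    if absent:
        raise ValueError(f"matched transcript(s) absent from TPM table: "
                         f"{absent}")
    return tpm.loc[tids].sum(axis=0).rename(match.probe_id)


def platform_concordance(agg_a: pd.Series, agg_b: pd.Series,
                         log_scale: bool = False) -> dict:
    """R² and p-value of the linear regression of one aggregate on the other.

    ``log_scale=True`` compares log2(TPM + 1) instead of raw TPM.  With
    fewer than 3 shared samples or zero variance in either vector, R² is
    undefined and reported as NaN.
    """
    common = agg_a.index.intersection(agg_b.index)
    if len(common) < 3:
        raise ValueError("concordance needs at least 3 shared samples")
    a, b = agg_a.loc[common].to_numpy(), agg_b.loc[common].to_numpy()
    if log_scale:
        a, b = np.log2(a + 1), np.log2(b + 1)
    out = {"n": int(len(common)), "log_scale": log_scale}
    if np.var(a) == 0 or np.var(b) == 0:
        warnings.warn("zero variance in an aggregate; R² undefined",
                      stacklevel=2)
        out.update(r_squared=np.nan, p_value=np.nan,
                   slope=np.nan, intercept=np.nan)
        return out
    fit = stats.linregress(b, a)
    out.update(r_squared=float(fit.rvalue ** 2), p_value=float(fit.pvalue),
               slope=float(fit.slope), intercept=float(fit.intercept))
    return out


# ---------------------------------------------------------------------------
# I/O

def read_transcripts_fasta(path,
                           exons: dict[str, list[tuple[int, int]]] | None = None
                           ) -> list[TranscriptModel]:
    """Read spliced transcript sequences from FASTA.

    Headers may carry ``gene=SYMBOL`` and ``strand=+/-`` tokens in the
    description; absent tokens default to the transcript's own id and '+'.
    ``exons`` (e.g. from :func:`read_transcript_exons_gtf`) attaches exon
    structure by transcript id.
    """
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        tokens = dict(t.split("=", 1) for t in rec.description.split()
                      if "=" in t)
        out.append(TranscriptModel(
            transcript_id=rec.id,
            gene_id=tokens.get("gene", rec.id),
            strand=tokens.get("strand", "+"),
            sequence=str(rec.seq),
            exons=(exons or {}).get(rec.id, []),
        ))
    return out


def read_transcript_exons_gtf(path) -> dict[str, list[tuple[int, int]]]:
    """Exon intervals per transcript id from a GTF (1-based closed)."""
    import pyranges as pr
    df = pr.read_gtf(str(path)).as_df()
    df = df[df["Feature"] == "exon"]
    exons: dict[str, list[tuple[int, int]]] = {}
    for tid, sub in df.groupby("transcript_id"):
        iv = sorted((int(s) + 1, int(e)) for s, e in
                    zip(sub["Start"], sub["End"]))  # pyranges holds 0-based starts
        exons[tid] = iv
    return exons


def read_tpm(path, fmt: str | None = None) -> pd.DataFrame:
    """Transcript × sample TPM table from TSV/CSV (first column = id)."""
    sep = "," if (fmt == "csv" or str(path).endswith(".csv")) else "\t"
    tpm = pd.read_csv(path, sep=sep, index_col=0)
    if (tpm.to_numpy() < 0).any():
        raise ValueError("TPM values must be non-negative")
    return tpm
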