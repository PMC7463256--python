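"""Ancient-DNA consensus curation.

Read filtering, duplicate removal, depth/region/multiallelic masking,
majority-rule consensus calling with completeness classification, and
terminal-damage profiling — the standard curation applied to mapped
ancient mitochondrial reads before phylogenetic analysis.

Conventions: positions are 0-based; region masks are half-open
intervals [start, end) (BED convention).  A consensus is classified
"complete" when strictly more than 80% of reference positions are
called (non-N) — the completeness bar used for including a specimen in
downstream analyses — at the default minimum depth of 3x.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import Fragment, ReadSet

__all__ = [
    "ConsensusResult",
    "filter_reads",
    "deduplicate",
    "call_consensus",
    "mask_high_coverage_multiallelic",
    "damage_profile",
    "site_counts_frame",
]

_BASES = "ACGT"

COMPLETENESS_THRESHOLD = 0.80
DEFAULT_MIN_DEPTH = 3
DEFAULT_MIN_LENGTH = 24
DEFAULT_MIN_MAPQ = 30


@dataclass
class ConsensusResult:
    sequence: str               # reference length, over {A,C,G,T,N}
    mask_reasons: list[str]     # none | low_depth | high_cov_multiallelic | region_mask | tie
    completeness: float         # fraction of non-N positions
    is_complete: bool           # completeness > 0.80

    def __post_init__(self):
        if not 0.0 <= self.completeness <= 1.0:
            raise ValueError("completeness outside [0, 1]")


def filter_reads(
    read_set: ReadSet,
    min_length: int = DEFAULT_MIN_LENGTH,
    min_mapq: int = DEFAULT_MIN_MAPQ,
) -> ReadSet:
    """Keep fragments with length >= min_length and MAPQ >= min_mapq.

    Both boundaries are inclusive; order is preserved.
    """
    if min_length < 0 or min_mapq < 0:
        raise ValueError("thresholds must be non-negative")
    return ReadSet(
        [f for f in read_set if f.length >= min_length and f.mapq >= min_mapq]
    )


def deduplicate(read_set: ReadSet) -> ReadSet:
    """One fragment per unique (start, end, strand) triple.

    PCR/optical duplicates share both 5' and 3' mapped coordinates;
    fragments sharing only one end are genuine distinct molecules and
    are kept.  Ties keep the highest-MAPQ fragment, then the first seen.
    """
    best: dict[tuple, tuple[int, int]] = {}  # key -> (index, mapq)
    for i, f in enumerate(read_set):
        key = (f.start, f.end, f.strand)
        if key not in best or f.mapq > best[key][1]:
            best[key] = (i, f.mapq)
    keep = sorted(i for i, _ in best.values())
    return ReadSet([read_set.fragments[i] for i in keep])


def _as_counts(site_counts) -> np.ndarray:
    counts = np.asarray(site_counts, dtype=np.int64)
    if counts.ndim != 2 or counts.shape[1] != 4:
        raise ValueError("site counts must have shape (length, 4) for A,C,G,T")
    if np.any(counts < 0):
        raise ValueError("negative base counts")
    return counts


def mask_high_coverage_multiallelic(
    site_counts,
    sd_multiplier: float = 3.0,
    min_minor_count: int = 2,
    covered_only: bool = True,
) -> set[int]:
    """Positions that are both coverage outliers and multiallelic.

    Read stacking in conserved regions (rRNAs, D-loop) inflates depth
    and mixes paralogous or contaminant bases; a position is masked when
    its depth exceeds mean + sd_multiplier*SD of per-position depth
    (computed over covered positions by default; set
    ``covered_only=False`` to include zero-depth positions) AND at least
    two bases each have >= min_minor_count supporting reads.
    """
    counts = _as_counts(site_counts)
    depth = counts.sum(axis=1)
    pool = depth[depth >= 1] if covered_only else depth
    if pool.size == 0:
        return set()
    cutoff = pool.mean() + sd_multiplier * pool.std(ddof=0)
    high = depth > cutoff
    multi = (counts >= min_minor_count).sum(axis=1) >= 2
    return set(int(i) for i in np.flatnonzero(high & multi))


def call_consensus(
    site_counts,
    min_depth: int = DEFAULT_MIN_DEPTH,
    region_mask=(),
    high_cov_positions=None,
) -> ConsensusResult:
    """Majority-rule consensus with N-masking.

    Per position the call is N when depth < min_depth, when the
    position lies in a masked region (e.g. the VNTR), when it was
    flagged as a high-coverage multiallelic site, or when the majority
    is tied; otherwise the strictly most frequent base.  Completeness
    is the non-N fraction over all reference positions and a sequence
    is "complete" when it exceeds 0.80.
    """
    counts = _as_counts(site_counts)
    L = counts.shape[0]
    depth = counts.sum(axis=1)
    top = counts.max(axis=1)
    argtop = counts.argmax(axis=1)
    tied = (counts == top[:, None]).sum(axis=1) > 1

    in_region = np.zeros(L, dtype=bool)
    for start, end in region_mask:
        if start < 0 or end > L or start >= end:
            raise ValueError(f"bad mask interval [{start}, {end}) for length {L}")
        in_region[start:end] = True
    high_cov = np.zeros(L, dtype=bool)
    if high_cov_positions:
        high_cov[np.fromiter(high_cov_positions, dtype=np.int64)] = True

    seq = np.array([_BASES[i] for i in argtop])
    reasons = np.full(L, "none", dtype=object)
    # precedence: explicit region mask, then depth, then stacking, then ties
    tie_mask = tied & (depth >= min_depth)
    seq[tie_mask] = "N"
    reasons[tie_mask] = "tie"
    seq[high_cov] = "N"
    reasons[high_cov] = "high_cov_multiallelic"
    low = depth < min_depth
    seq[low] = "N"
    reasons[low] = "low_depth"
    seq[in_region] = "N"
    reasons[in_region] = "region_mask"

    completeness = float(np.mean(seq != "N")) if L else 0.0
    return ConsensusResult(
        sequence="".join(seq),
        mask_reasons=list(reasons),
        completeness=completeness,
        is_complete=completeness > COMPLETENESS_THRESHOLD,
    )


def damage_profile(read_set: ReadSet, reference: str, window: int = 15) -> pd.DataFrame:
    """Terminal substitution frequencies characteristic of aDNA damage.

    For each offset 0..window-1 from the fragment 5' end, the fraction
    of reference-C positions read as T; symmetrically G->A from the 3'
    end.  Offsets where no reference C (resp. G) is covered are NaN,
    not zero — absence of evidence is reported as missing.
    """
    ref = np.array(list(reference.upper()))
    c_cov = np.zeros(window)
    ct = np.zeros(window)
    g_cov = np.zeros(window)
    ga = np.zeros(window)
    for frag in read_set:
        fseq = np.array(list(frag.sequence))
        rseq = ref[frag.start : frag.end]
        w5 = min(window, frag.length)
        is_c = rseq[:w5] == "C"
        c_cov[:w5] += is_c
        ct[:w5] += is_c & (fseq[:w5] == "T")
        tail_r = rseq[::-1][:w5]
        tail_f = fseq[::-1][:w5]
        is_g = tail_r == "G"
        g_cov[:w5] += is_g
        ga[:w5] += is_g & (tail_f == "A")
    with np.errstate(invalid="ignore", divide="ignore"):
        f_ct = np.where(c_cov > 0, ct / np.maximum(c_cov, 1), np.nan)
        f_ga = np.where(g_cov > 0, ga / np.maximum(g_cov, 1), np.nan)
    return pd.DataFrame(
        {
            "offset": np.arange(window),
            "ct_5p": f_ct,
            "n_c_5p": c_cov.astype(int),
            "ga_3p": f_ga,
            "n_g_3p": g_cov.astype(int),
        }
    )


def site_counts_frame(counts, reference: str | None = None) -> pd.DataFrame:
    """SiteCounts as a tidy table (position, A, C, G, T, depth[, ref])."""
    counts = _as_counts(counts)
    df = pd.DataFrame(counts, columns=list(_BASES))
    df.insert(0, "position", np.arange(len(df)))
    df["depth"] = counts.sum(axis=1)
    if reference is not None:
        if len(reference) != len(df):
            raise ValueError("reference length != counts length")
        df["ref"] = list(reference.upper())
    return df
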