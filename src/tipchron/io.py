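"""Standard-format I/O: FASTA, Newick/NEXUS, TSV tables, BED masks.

All interval formats are 0-based half-open (BED convention); sequences
are folded to upper case on read.  Trees are written with branch
lengths in years.
"""

from __future__ import annotations

from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .curation import site_counts_frame
from .dating import TipDate, TipDateSpec, Trace
from .phylo import Alignment
from .tree import TimeTree

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_tree",
    "write_tree",
    "read_tip_dates",
    "write_tip_dates",
    "read_bed",
    "write_bed",
    "read_site_counts",
    "write_site_counts",
    "write_trace",
]

_ALLOWED = set("ACGTN-")


def read_fasta(path) -> Alignment:
    """Read an aligned FASTA into an Alignment (upper-cased, validated)."""
    ids, rows = [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if "U" in seq:
            raise ValueError(f"record {rec.id}: RNA alphabet (U) is not supported")
        bad = set(seq) - _ALLOWED
        if bad:
            raise ValueError(f"record {rec.id}: disallowed characters {sorted(bad)}")
        ids.append(rec.id)
        rows.append(seq)
    if not ids:
        raise ValueError(f"no FASTA records in {path}")
    lengths = {len(r) for r in rows}
    if len(lengths) > 1:
        offenders = [i for i, r in zip(ids, rows) if len(r) != len(rows[0])]
        raise ValueError(f"ragged alignment; offending records: {offenders}")
    return Alignment(ids, rows)


def write_fasta(alignment: Alignment, path) -> None:
    records = [
        SeqRecord(Seq(row), id=name, description="")
        for name, row in zip(alignment.ids, alignment.rows)
    ]
    SeqIO.write(records, str(path), "fasta")


def read_tree(path, schema: str = "newick", tip_ages: dict | None = None) -> TimeTree:
    """Read a rooted binary tree; node ages recomputed from path lengths.

    ``tip_ages`` (label -> years before youngest tip, e.g. from a
    tip-date table) overrides the path-derived tip ages.
    """
    dtree = dendropy.Tree.get(path=str(path), schema=schema)
    return TimeTree.from_dendropy(dtree, tip_ages=tip_ages)


def write_tree(tree: TimeTree, path, schema: str = "newick") -> None:
    if schema == "newick":
        Path(path).write_text(tree.to_newick() + "\n")
    elif schema == "nexus":
        dtree = tree.to_dendropy()
        dtree.write(path=str(path), schema="nexus")
    else:
        raise ValueError(f"unknown tree schema {schema!r}")


_TIP_COLS = ["id", "status", "age_bp", "lower_bp", "upper_bp", "prior_shape", "prior_scale"]


def read_tip_dates(path, bounds_absolute: bool = True) -> TipDateSpec:
    """Tip-date table TSV -> TipDateSpec.

    Columns: id, status (fixed|estimated), age_bp (fixed tips),
    lower_bp, upper_bp, prior_shape, prior_scale (estimated tips; blank
    fields take the defaults).  ``reference_age`` is the youngest fixed
    tip's age in years BP.
    """
    df = pd.read_csv(path, sep="\t")
    missing = {"id", "status"} - set(df.columns)
    if missing:
        raise ValueError(f"tip-date table lacks columns: {sorted(missing)}")
    tips = {}
    defaults = TipDate(status="estimated")
    for _, row in df.iterrows():
        status = str(row["status"])
        kwargs = {"status": status}
        if status == "fixed":
            kwargs["point_age"] = float(row["age_bp"])
        for col, attr in [
            ("lower_bp", "lower"),
            ("upper_bp", "upper"),
            ("prior_shape", "prior_shape"),
            ("prior_scale", "prior_scale"),
        ]:
            if col in df.columns and pd.notna(row.get(col)):
                kwargs[attr] = float(row[col])
            else:
                kwargs[attr] = getattr(defaults, attr)
        tips[str(row["id"])] = TipDate(**kwargs)
    fixed_ages = [t.point_age for t in tips.values() if t.status == "fixed"]
    reference = min(fixed_ages) if fixed_ages else 0.0
    return TipDateSpec(tips, reference_age=reference, bounds_absolute=bounds_absolute)


def write_tip_dates(spec: TipDateSpec, path) -> None:
    rows = []
    for label, t in spec.tips.items():
        rows.append(
            {
                "id": label,
                "status": t.status,
                "age_bp": t.point_age if t.point_age is not None else "",
                "lower_bp": t.lower,
                "upper_bp": t.upper,
                "prior_shape": t.prior_shape,
                "prior_scale": t.prior_scale,
            }
        )
    pd.DataFrame(rows, columns=_TIP_COLS).to_csv(path, sep="\t", index=False)


def read_bed(path) -> list[tuple[int, int]]:
    """BED intervals (chrom ignored; 0-based half-open)."""
    out = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed BED line: {line!r}")
        start, end = int(parts[1]), int(parts[2])
        if start >= end or start < 0:
            raise ValueError(f"bad BED interval [{start}, {end})")
        out.append((start, end))
    return out


def write_bed(intervals, path, chrom: str = "ref") -> None:
    lines = [f"{chrom}\t{s}\t{e}" for s, e in intervals]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_site_counts(path) -> np.ndarray:
    df = pd.read_csv(path, sep="\t")
    need = {"position", "A", "C", "G", "T"}
    if not need <= set(df.columns):
        raise ValueError(f"site-count table lacks columns: {sorted(need - set(df.columns))}")
    df = df.sort_values("position")
    if not np.array_equal(df["position"].to_numpy(), np.arange(len(df))):
        raise ValueError("positions must be contiguous from 0")
    return df[["A", "C", "G", "T"]].to_numpy(dtype=np.int64)


def write_site_counts(counts, path, reference: str | None = None) -> None:
    site_counts_frame(counts, reference=reference).to_csv(path, sep="\t", index=False)


def write_trace(trace: Trace, path) -> None:
    """Tab-separated trace log (state, posterior, likelihood, prior, ...)."""
    df = trace.data.rename(columns={"step": "state"})
    df.to_csv(path, sep="\t", index=False)
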