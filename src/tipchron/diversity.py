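"""Clade-level nucleotide diversity from F84 pairwise distances.

Nucleotide diversity (pi) of a clade is the mean of all pairwise F84
distances between its members, in substitutions per site, with missing
data deleted pairwise.  The spread ("SD") is the sample standard
deviation across those pairwise distances.  Two-member groups report
their single pairwise value as a distance rather than a diversity.
"""

from __future__ import annotations

import itertools
import warnings

import numpy as np
import pandas as pd

from .phylo import Alignment, distance_matrix, empirical_base_freqs, f84_distance

__all__ = ["nucleotide_diversity", "clade_distance_table"]


def nucleotide_diversity(
    alignment: Alignment,
    members: list[str],
    freq_mode: str = "global",
    sd_mode: str = "sample",
) -> tuple[float, float, int]:
    """(pi, sd, n_pairs) over a set of alignment members.

    ``sd_mode``: "sample" uses the n-1 denominator, "population" uses
    n.  Undefined (saturated / non-overlapping) pairs are excluded with
    a warning and reflected in ``n_pairs``; with a single usable pair
    the sd is NaN.
    """
    members = list(members)
    if len(members) < 2:
        raise ValueError("need at least 2 members")
    missing = set(members) - set(alignment.ids)
    if missing:
        raise ValueError(f"members absent from alignment: {sorted(missing)}")
    if sd_mode not in ("sample", "population"):
        raise ValueError("sd_mode must be 'sample' or 'population'")

    codes = {i: alignment.codes[alignment.ids.index(i)] for i in members}
    freqs = empirical_base_freqs(alignment) if freq_mode == "global" else None
    dists = []
    n_undefined = 0
    for a, b in itertools.combinations(members, 2):
        d = f84_distance(codes[a], codes[b], freqs=freqs)
        if np.isnan(d):
            n_undefined += 1
        else:
            dists.append(d)
    if n_undefined:
        warnings.warn(f"{n_undefined} undefined pairwise distances excluded")
    if not dists:
        raise ValueError("all pairwise distances are undefined")
    dists = np.asarray(dists)
    pi = float(dists.mean())
    if len(dists) == 1:
        sd = float("nan")
    else:
        sd = float(dists.std(ddof=1 if sd_mode == "sample" else 0))
    return pi, sd, len(dists)


def clade_distance_table(
    alignment: Alignment,
    clade_assignment: dict[str, str],
    variants: list[dict] | None = None,
    freq_mode: str = "global",
    sd_mode: str = "sample",
) -> dict[str, pd.DataFrame]:
    """Pairwise-distance long table plus per-variant diversity summaries.

    ``clade_assignment`` maps tip label -> clade label; only assigned
    tips enter the table.  Each variant is a mapping with keys ``name``,
    ``clade`` and optionally ``exclude`` (tips dropped for that
    variant), reproducing include/exclude comparisons such as a clade
    with and without a geographically outlying specimen.

    Returns {"pairs": ..., "summary": ...}.
    """
    unknown = set(clade_assignment) - set(alignment.ids)
    if unknown:
        raise ValueError(f"assigned tips absent from alignment: {sorted(unknown)}")
    tips = [i for i in alignment.ids if i in clade_assignment]
    dm = distance_matrix(alignment.subset(tips), freq_mode=freq_mode)
    idx = {l: i for i, l in enumerate(dm.labels)}

    rows = []
    for a, b in itertools.combinations(sorted(tips), 2):
        rows.append(
            {
                "tip_a": a,
                "tip_b": b,
                "clade_a": clade_assignment[a],
                "clade_b": clade_assignment[b],
                "distance": dm.values[idx[a], idx[b]],
            }
        )
    pairs = pd.DataFrame(rows)

    if variants is None:
        clades = sorted(set(clade_assignment.values()))
        variants = [{"name": c, "clade": c} for c in clades]
    summaries = []
    for var in variants:
        clade = var["clade"]
        excluded = set(var.get("exclude", ()))
        members = [
            t for t in tips if clade_assignment[t] == clade and t not in excluded
        ]
        if any(e not in alignment.ids for e in excluded):
            raise ValueError(f"variant {var.get('name')}: unknown excluded tip")
        if len(members) < 2:
            raise ValueError(
                f"variant {var.get('name', clade)}: fewer than 2 members"
            )
        pi, sd, n_pairs = nucleotide_diversity(
            alignment, members, freq_mode=freq_mode, sd_mode=sd_mode
        )
        summaries.append(
            {
                "variant": var.get("name", clade),
                "clade": clade,
                "statistic": "distance" if len(members) == 2 else "pi",
                "value": pi,
                "sd": sd,
                "n_members": len(members),
                "n_pairs": n_pairs,
            }
        )
    return {"pairs": pairs, "summary": pd.DataFrame(summaries)}
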