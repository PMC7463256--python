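"""Stage orchestration: simulate -> curate -> date -> diversity.

A single YAML config drives all stages; every run directory gets a
manifest recording the seed, a hash of the resolved config, package
and library versions, and input checksums, so a rerun with the same
config and seed reproduces byte-identical traces.
"""

from __future__ import annotations

import hashlib
import json
import platform

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import io as tio
from .curation import call_consensus, mask_high_coverage_multiallelic
from .dating import ClockPriors, McmcConfig, individual_dating, joint_dating
from .diversity import clade_distance_table
from .phylo import SubstModel, empirical_base_freqs
from .simulate import SimConfig, degrade_to_reads, make_pileup, simulate_dataset
from .tree import TimeTree

__all__ = ["run_pipeline", "load_config", "STAGES"]

STAGES = ("simulate", "curate", "date-joint", "date-individual", "diversity")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError("config must be a YAML mapping")
    return cfg


def _config_hash(cfg: dict) -> str:
    canon = json.dumps(cfg, sort_keys=True, default=str).encode()
    return hashlib.sha256(canon).hexdigest()[:16]


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _require(cfg: dict, stage: str, key: str):
    if key not in cfg:
        raise PipelineError(stage, f"missing config key {key!r}")
    return cfg[key]


def _input_path(cfg, stage, key) -> Path:
    p = Path(_require(cfg, stage, key))
    if not p.exists():
        raise PipelineError(stage, f"input file does not exist: {p}")
    return p


def run_pipeline(config: dict, outdir, stages=("all",), seed: int | None = None) -> Path:
    """Execute the requested stages in dependency order.

    ``config`` is the parsed YAML mapping with optional per-stage
    sections; ``seed`` overrides ``config['seed']``.  Returns the
    artifact directory.  Any stage failure aborts with the stage name
    and the offending input.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0) if seed is None else seed)
    wanted = list(STAGES) if "all" in stages else [s for s in STAGES if s in stages]
    if not wanted:
        raise ValueError(f"no recognised stages in {stages}")

    manifest = {
        "tipchron": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "seed": seed,
        "config_hash": _config_hash(config),
        "stages": wanted,
        "inputs": {},
        "outputs": [],
    }

    def emit(path: Path):
        manifest["outputs"].append(str(path.relative_to(outdir)))

    for stage in wanted:
        scfg = dict(config.get(stage.replace("-", "_"), {}))
        if stage == "simulate":
            sim = SimConfig(seed=seed, **{
                k: v for k, v in scfg.items()
                if k in ("n_tips", "tip_ages", "pop_size", "rate", "kappa",
                         "alpha", "base_freqs", "seq_length", "missing_frac")
            })
            aln, truth = simulate_dataset(sim)
            tio.write_fasta(aln, outdir / "simulated_alignment.fasta")
            tio.write_tree(truth.true_tree, outdir / "true_tree.nwk")
            pd.DataFrame(
                {
                    "tip": list(truth.true_tip_ages),
                    "true_age": list(truth.true_tip_ages.values()),
                }
            ).to_csv(outdir / "ground_truth.tsv", sep="\t", index=False)
            reads = degrade_to_reads(
                aln.rows[0],
                deamination_rate=float(scfg.get("deamination_rate", 0.0)),
                coverage=float(scfg.get("coverage", 10.0)),
                seed=seed + 17,
            )
            counts = make_pileup(reads, aln.length)
            tio.write_site_counts(counts, outdir / "site_counts.tsv",
                                  reference=aln.rows[0])
            for name in ("simulated_alignment.fasta", "true_tree.nwk",
                         "ground_truth.tsv", "site_counts.tsv"):
                emit(outdir / name)

        elif stage == "curate":
            counts_path = (
                outdir / "site_counts.tsv"
                if (outdir / "site_counts.tsv").exists() and "counts" not in scfg
                else _input_path(scfg, stage, "counts")
            )
            counts = tio.read_site_counts(counts_path)
            manifest["inputs"][str(counts_path)] = _checksum(counts_path)
            mask = []
            if scfg.get("mask"):
                mask = tio.read_bed(_input_path(scfg, stage, "mask"))
            high = mask_high_coverage_multiallelic(counts)
            result = call_consensus(
                counts,
                min_depth=int(scfg.get("min_depth", 3)),
                region_mask=mask,
                high_cov_positions=high,
            )
            from .phylo import Alignment

            tio.write_fasta(
                Alignment([scfg.get("name", "consensus")], [result.sequence]),
                outdir / "consensus.fasta",
            )
            pd.DataFrame(
                {"position": range(len(result.mask_reasons)),
                 "reason": result.mask_reasons}
            ).to_csv(outdir / "mask_report.tsv", sep="\t", index=False)
            (outdir / "completeness.json").write_text(
                json.dumps(
                    {
                        "completeness": result.completeness,
                        "is_complete": result.is_complete,
                    },
                    indent=2,
                )
            )
            for name in ("consensus.fasta", "mask_report.tsv", "completeness.json"):
                emit(outdir / name)

        elif stage in ("date-joint", "date-individual"):
            aln_path = (
                outdir / "simulated_alignment.fasta"
                if (outdir / "simulated_alignment.fasta").exists()
                and "alignment" not in scfg
                else _input_path(scfg, stage, "alignment")
            )
            dates_path = _input_path(scfg, stage, "tip_dates")
            aln = tio.read_fasta(aln_path)
            spec = tio.read_tip_dates(dates_path)
            manifest["inputs"][str(aln_path)] = _checksum(aln_path)
            manifest["inputs"][str(dates_path)] = _checksum(dates_path)
            rel_ages = {}
            for label in spec.fixed_labels():
                rel_ages[label] = spec.rel_age(label)
            if scfg.get("fixed_topology"):
                tree = tio.read_tree(
                    _input_path(scfg, stage, "fixed_topology"), tip_ages=None
                )
            else:
                from .simulate import simulate_coalescent_tree

                # random start genealogy: tip i of the simulator carries
                # the start age of aln.ids[i], so labels map positionally
                start_ages = [
                    rel_ages.get(l, 0.5 * sum(spec.rel_bounds(l))) for l in aln.ids
                ]
                tree = simulate_coalescent_tree(
                    np.asarray(start_ages), float(scfg.get("start_pop", 1e5)),
                    seed=seed + 29,
                )
                tree = TimeTree(list(aln.ids), tree.parent, tree.children, tree.ages)
            mcfg = McmcConfig(
                chain_length=int(scfg.get("chain_length", 100_000)),
                sample_every=int(scfg.get("sample_every", 100)),
                n_replicates=int(scfg.get("n_replicates", 2)),
                seed=seed,
            )
            model = SubstModel(
                kappa=float(scfg.get("kappa", 20.0)),
                base_freqs=empirical_base_freqs(aln),
                alpha=float(scfg.get("alpha", 0.5)),
                rate=float(scfg.get("start_rate", 2e-8)),
            )
            fn = joint_dating if stage == "date-joint" else individual_dating
            result = fn(aln, tree, spec, ClockPriors(), model, mcfg)
            tag = stage.replace("-", "_")
            result.summary.to_csv(outdir / f"{tag}_summary.tsv", sep="\t", index=False)
            for r, tr in enumerate(result.traces):
                tio.write_trace(tr, outdir / f"{tag}_chain{r}.log")
                emit(outdir / f"{tag}_chain{r}.log")
            emit(outdir / f"{tag}_summary.tsv")

        elif stage == "diversity":
            aln_path = _input_path(scfg, stage, "alignment")
            clades_path = _input_path(scfg, stage, "clades")
            aln = tio.read_fasta(aln_path)
            cl = pd.read_csv(clades_path, sep="\t")
            assignment = dict(zip(cl["tip"].astype(str), cl["clade"].astype(str)))
            manifest["inputs"][str(clades_path)] = _checksum(clades_path)
            tables = clade_distance_table(aln, assignment,
                                          variants=scfg.get("variants"))
            tables["pairs"].to_csv(outdir / "pairwise_distances.tsv", sep="\t",
                                   index=False)
            tables["summary"].to_csv(outdir / "diversity_summary.tsv", sep="\t",
                                     index=False)
            emit(outdir / "pairwise_distances.tsv")
            emit(outdir / "diversity_summary.tsv")

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return outdir
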