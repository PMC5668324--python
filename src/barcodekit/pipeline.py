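"""Full-study orchestration: per-locus characteristics, distance and
barcode-gap summaries, identification rates over every locus combination,
diagnostic rules, CAPS assays and trees, bundled as TSV/JSON/newick output.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import align_stats, classify, diagnostics, distances, trees
from .seqio import BarcodeDataset, concatenate, enumerate_combinations, load_manifest

__all__ = ["RunConfig", "run_report"]

log = logging.getLogger("barcodekit")


@dataclass
class RunConfig:
    """Configuration of one full evaluation run."""

    manifest: str | Path | None = None
    dataset: BarcodeDataset | None = None
    loci: str | Sequence[Sequence[str]] = "all-combinations"
    methods: tuple[str, ...] = ("BM", "BCM", "ASB")
    percentile: float = 95.0
    threshold: float | None = None
    outgroup_ids: tuple[str, ...] = ()
    tree_loci: tuple[str, ...] | None = None
    mp_replicates: int = 10
    bootstrap_replicates: int = 100
    seed: int | None = None
    outdir: str | Path | None = None
    run_diagnostics: bool = True
    run_trees: bool = True

    def resolve_dataset(self) -> BarcodeDataset:
        if self.dataset is not None:
            return self.dataset
        if self.manifest is None:
            raise ValueError("RunConfig needs a dataset or a manifest path")
        return load_manifest(self.manifest)


def _locus_sets(config: RunConfig, dataset: BarcodeDataset) -> list[tuple[str, ...]]:
    names = sorted(dataset.loci)
    singles = [(n,) for n in names]
    if config.loci == "all-combinations":
        return singles + (enumerate_combinations(names) if len(names) >= 2 else [])
    return [tuple(ls) for ls in config.loci]


def run_report(config: RunConfig) -> dict:
    """Run the whole evaluation; returns the machine-readable bundle.

    When ``config.outdir`` is set, TSV tables, newick trees and the JSON
    bundle are also written there.  Independent stages that fail are reported
    in the bundle's ``errors`` and the run continues.
    """
    dataset = config.resolve_dataset()
    bundle: dict = {"seed": config.seed, "errors": {}}

    stats_rows = []
    for name in sorted(dataset.loci):
        s = align_stats.compute_stats(dataset.loci[name])
        stats_rows.append({"locus": name, **s.__dict__})
    bundle["locus_stats"] = stats_rows

    locus_sets = _locus_sets(config, dataset)
    rate_rows, gap_rows = [], []
    for ls in locus_sets:
        label = "+".join(ls)
        try:
            aln = concatenate(dataset, list(ls))
            m = distances.distance_matrix(aln)
            means = distances.divergence_means(m, aln.species_map)
            for summary in distances.species_summaries(m, aln.species_map):
                gap_rows.append({"loci": label, **summary.__dict__, **means})
            for method in config.methods:
                r = classify.rates_from_results(
                    classify.classify_all(
                        m,
                        aln.species_map,
                        method,
                        threshold=config.threshold,
                        percentile=config.percentile,
                    )
                )
                rate_rows.append(
                    {
                        "loci": label,
                        "method": method,
                        "correct_pct": round(r.correct_pct, 2),
                        "misidentified_pct": round(r.misidentified_pct, 2),
                        "not_identified_pct": round(r.not_identified_pct, 2),
                    }
                )
        except Exception as exc:  # keep independent stages running
            log.warning("stage %s failed: %s", label, exc)
            bundle["errors"][label] = str(exc)
    bundle["identification_rates"] = rate_rows
    bundle["gap_summaries"] = gap_rows

    if config.run_diagnostics:
        diag_rows, caps_rows, rule_rows = [], [], []
        for name in sorted(dataset.loci):
            aln = dataset.loci[name]
            try:
                for ch in diagnostics.find_diagnostic_characters(aln):
                    diag_rows.append(
                        {
                            "locus": name,
                            "species": ch.species,
                            "position": ch.position,
                            "state": ch.state,
                        }
                    )
                for assay in diagnostics.design_caps(aln):
                    caps_rows.append({**assay.__dict__})
                induced = diagnostics.induce_rules(aln, seed=config.seed)
                for rule in induced.rules:
                    rule_rows.append(
                        {
                            "locus": name,
                            "species": rule.species,
                            "conjuncts": ";".join(
                                f"{p}={s}" for p, s in rule.conjuncts
                            ),
                            "test_correct_pct": round(induced.test_correct_pct, 2),
                        }
                    )
            except Exception as exc:
                log.warning("diagnostics on %s failed: %s", name, exc)
                bundle["errors"][f"diagnostics:{name}"] = str(exc)
        bundle["diagnostic_characters"] = diag_rows
        bundle["caps_assays"] = caps_rows
        bundle["rules"] = rule_rows

    if config.run_trees:
        tree_loci = config.tree_loci or tuple(sorted(dataset.loci))
        label = "+".join(tree_loci)
        try:
            aln = concatenate(dataset, list(tree_loci))
            m = distances.distance_matrix(aln)
            nj = trees.nj_tree(
                m, outgroup_ids=config.outgroup_ids or None
            )
            mp = trees.mp_search(
                aln,
                strategy="auto" if len(aln.records) <= 12 else "hillclimb",
                seed=config.seed,
                replicates=config.mp_replicates,
            )
            consensus = mp.consensus
            supported = trees.bootstrap_support(
                aln,
                builder="nj",
                n_replicates=config.bootstrap_replicates,
                seed=config.seed,
            )
            mono = {}
            if config.outgroup_ids:
                smap = aln.species_map
                outgroup_species = {
                    smap[i] for i in config.outgroup_ids if i in smap
                }
                for sp in sorted(set(smap.values()) - outgroup_species):
                    mono[sp] = trees.is_monophyletic(
                        mp.best_trees[0], smap, sp, config.outgroup_ids
                    )
            bundle["trees"] = {
                "loci": label,
                "mp_length": mp.length,
                "ci": mp.ci,
                "ri": mp.ri,
                "rc": mp.rc,
                "n_characters": mp.n_characters,
                "n_informative": mp.n_informative,
                "n_best_trees": len(mp.best_trees),
                "consensus_newick": consensus.as_string(schema="newick").strip(),
                "nj_newick": nj.as_string(schema="newick").strip(),
                "nj_bootstrap_newick": supported.as_string(schema="newick").strip(),
                "monophyly": mono,
            }
        except Exception as exc:
            log.warning("tree stage failed: %s", exc)
            bundle["errors"][f"trees:{label}"] = str(exc)

    if config.outdir is not None:
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(stats_rows).to_csv(
            outdir / "locus_stats.tsv", sep="\t", index=False
        )
        pd.DataFrame(rate_rows).to_csv(
            outdir / "identification_rates.tsv", sep="\t", index=False
        )
        pd.DataFrame(gap_rows).to_csv(
            outdir / "gap_summaries.tsv", sep="\t", index=False
        )
        if "trees" in bundle:
            (outdir / "consensus.nwk").write_text(
                bundle["trees"]["consensus_newick"] + "\n"
            )
            (outdir / "nj.nwk").write_text(bundle["trees"]["nj_newick"] + "\n")
        (outdir / "report.json").write_text(json.dumps(bundle, indent=2, default=str))
    return bundle
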