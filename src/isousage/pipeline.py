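"""End-to-end orchestration: many genes, many samples, two groups.

The analysis is two-step: per sample, the fragment length distribution
is estimated once and each gene's usage is then fitted by EM; per gene,
the two groups of usage estimates are compared on ilr coordinates and
p-values are adjusted across all testable genes of the comparison.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .alignments import (
    ReadFilters,
    build_compatibility,
    estimate_fragment_length_distribution,
    load_read_pairs,
)
from .annotation import parse_annotation
from .twosample import DifferentialUsage, adjust_pvalues
from .usage import IsoformUsageModel

logger = logging.getLogger(__name__)

__all__ = ["RunManifest", "run_analysis", "merge_technical_replicates"]


@dataclass
class RunManifest:
    """Inputs and settings of one two-group comparison.

    ``group0``/``group1`` list one entry per biological replicate; an
    entry may itself be a list of technical-replicate BAMs, which are
    pooled before estimation.
    """

    annotation: str
    group0: list
    group1: list
    method: str = "SKK"
    eps: float = 1e-4
    adjustment: str = "bonferroni"
    alpha: float = 0.05
    min_reads: int = 10
    permutation_B: int | None = None
    seed: int = 0
    filters: ReadFilters = field(default_factory=ReadFilters)

    def __post_init__(self):
        if len(self.group0) < 2 or len(self.group1) < 2:
            raise ValueError("at least two biological replicates per group")
        for entry in list(self.group0) + list(self.group1):
            for path in [entry] if isinstance(entry, str) else entry:
                if not Path(path).exists():
                    raise FileNotFoundError(path)
        if not Path(self.annotation).exists():
            raise FileNotFoundError(self.annotation)


def merge_technical_replicates(pair_lists):
    """Pool read pairs of one biological replicate's technical replicates.

    Read-name collisions across files are suffix-disambiguated with a
    warning (the estimation step treats pairs independently).
    """
    merged = []
    seen = set()
    clashes = 0
    for i, pairs in enumerate(pair_lists):
        for pair in pairs:
            rid = pair.read_id
            if rid in seen:
                clashes += 1
                from dataclasses import replace

                pair = replace(pair, read_id=f"{rid}/tr{i}")
            seen.add(pair.read_id)
            merged.append(pair)
    if clashes:
        logger.warning("%d read-name collisions suffix-disambiguated", clashes)
    return merged


def _load_gene_pairs(entry, gene, filters):
    paths = [entry] if isinstance(entry, str) else list(entry)
    lists = []
    for path in paths:
        with pysam.AlignmentFile(path) as af:
            pairs, _ = load_read_pairs(af, gene, filters)
        lists.append(pairs)
    return merge_technical_replicates(lists) if len(lists) > 1 else lists[0]


def _check_chroms(manifest, genes):
    ann_chroms = {g.chrom for g in genes.values()}
    for entry in list(manifest.group0) + list(manifest.group1):
        path = entry if isinstance(entry, str) else entry[0]
        with pysam.AlignmentFile(path) as af:
            bam_chroms = set(af.references)
        missing = ann_chroms - bam_chroms
        if missing == ann_chroms:
            raise ValueError(
                f"{path}: no annotation chromosome present in BAM "
                f"(annotation uses {sorted(ann_chroms)})"
            )


def run_analysis(manifest: RunManifest, outdir: str | None = None):
    """Run the full two-step analysis described by a manifest.

    Returns ``(results, usage, summary)``: the per-gene test table, the
    per-gene-per-sample usage table, and a counter summary.  With
    ``outdir`` set, writes ``results.tsv``, ``usage.tsv`` and
    ``manifest.json`` there.
    """
    genes = parse_annotation(manifest.annotation)
    _check_chroms(manifest, genes)
    entries = [("0", j, e) for j, e in enumerate(manifest.group0)] + [
        ("1", j, e) for j, e in enumerate(manifest.group1)
    ]

    flds = {}
    for grp, j, entry in entries:
        paths = [entry] if isinstance(entry, str) else list(entry)
        flds[(grp, j)] = estimate_fragment_length_distribution(
            paths, genes, filters=manifest.filters
        )

    usage_rows = []
    estimates: dict[str, dict[str, list]] = {}
    summary = {"tested": 0, "untestable": 0, "single_isoform": 0, "insufficient": 0}
    skipped = {}
    for gid, gene in genes.items():
        if gene.K == 1:
            summary["single_isoform"] += 1
            skipped[gid] = "single_isoform"
            continue
        per_group: dict[str, list] = {"0": [], "1": []}
        for grp, j, entry in entries:
            pairs = _load_gene_pairs(entry, gene, manifest.filters)
            compat = build_compatibility(pairs, gene)
            if compat.n_reads == 0:
                continue
            model = IsoformUsageModel(
                compat, flds[(grp, j)], [iso.length for iso in gene.isoforms]
            )
            res = model.fit(min_reads=manifest.min_reads, seed=manifest.seed)
            if "insufficient_reads" in res.flags:
                summary["insufficient"] += 1
                continue
            per_group[grp].append(res)
            for iid, th, p in zip(gene.isoform_ids, res.theta, res.p_hat):
                usage_rows.append(
                    {
                        "gene_id": gid,
                        "group": grp,
                        "sample": j,
                        "isoform_id": iid,
                        "theta_hat": th,
                        "p_hat": p,
                        "n_reads": res.n_reads,
                        "converged": res.converged,
                    }
                )
        estimates[gid] = per_group

    result_rows = []
    for gid, per_group in estimates.items():
        gene = genes[gid]
        if len(per_group["0"]) < 2 or len(per_group["1"]) < 2:
            summary["untestable"] += 1
            result_rows.append(
                {
                    "gene_id": gid,
                    "K_tested": np.nan,
                    "method": manifest.method,
                    "statistic": np.nan,
                    "p_value": np.nan,
                    "group0_usage": "",
                    "group1_usage": "",
                    "flags": "untestable:insufficient_samples",
                }
            )
            continue
        du = DifferentialUsage.from_estimates(
            per_group["0"], per_group["1"], eps=manifest.eps
        )
        res = du.fit(
            method=manifest.method,
            permutation_B=manifest.permutation_B,
            seed=manifest.seed,
        )
        if res.testable:
            summary["tested"] += 1
        else:
            summary["untestable"] += 1
        fmt = lambda v: ",".join(f"{x:.6g}" for x in v) if v is not None else ""
        result_rows.append(
            {
                "gene_id": gid,
                "K_tested": len(res.kept_isoforms),
                "method": res.method,
                "statistic": res.statistic,
                "p_value": res.p_value,
                "group0_usage": fmt(res.group_means[0] if res.group_means else None),
                "group1_usage": fmt(res.group_means[1] if res.group_means else None),
                "flags": ";".join(res.result.flags),
            }
        )

    results = pd.DataFrame(result_rows).sort_values("gene_id").reset_index(drop=True)
    if len(results):
        results["p_adjusted"] = adjust_pvalues(
            results["p_value"].to_numpy(), manifest.adjustment
        )
    usage = pd.DataFrame(usage_rows)
    summary["skipped"] = skipped

    if outdir is not None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        results.to_csv(out / "results.tsv", sep="\t", index=False)
        usage.to_csv(out / "usage.tsv", sep="\t", index=False)
        manifest_dict = {
            k: v for k, v in vars(manifest).items() if k != "filters"
        }
        (out / "manifest.json").write_text(json.dumps(manifest_dict, indent=2))
    logger.info(
        "analysis complete: %d tested, %d untestable, %d single-isoform",
        summary["tested"],
        summary["untestable"],
        summary["single_isoform"],
    )
    return results, usage, summary
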