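"""End-to-end run: VCF in, filter accounting + ASE tables out.

One invocation analyses one call set (one tissue).  Multi-tissue overlap
and cross-tissue gene scores are a separate combine step over finished
run directories.  Outputs are deterministic: identical inputs and config
produce byte-identical files.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import pandas as pd

from .ase_stats import MdfdrResult, MetaResult, run_mdfdr, run_meta_analysis
from .filtering import FilterConfig, InformativeSnp, collect_informative
from .summaries import ase_frequency, direction_concordance, reference_allele_ratio
from .vcf_io import read_vcf, write_report

__all__ = ["RunConfig", "RunResult", "run", "combine_runs"]

logger = logging.getLogger("asedetect")


@dataclass(frozen=True)
class RunConfig:
    """Effective configuration of one detection run (echoed in output headers)."""

    filters: FilterConfig = field(default_factory=FilterConfig)
    alpha: float = 0.05
    model: Literal["meta", "mdfdr", "both"] = "both"
    screening: Literal["sidak", "fisher"] = "sidak"
    denominator: Literal["testable", "all_samples"] = "testable"

    def provenance(self) -> dict:
        out = {k: v for k, v in asdict(self.filters).items()}
        out.update(alpha=self.alpha, model=self.model, screening=self.screening,
                   denominator=self.denominator)
        return out


@dataclass
class RunResult:
    samples: list[str]
    informative: list[InformativeSnp]
    accounting: object
    meta: list[MetaResult] | None
    mdfdr: list[MdfdrResult] | None
    outdir: Path


def _write_informative(informative, prov, path) -> None:
    rows = []
    for snp in informative:
        chrom, pos, ref, alt = snp.key()
        total = int(snp.ref_counts.sum() + snp.alt_counts.sum())
        rows.append(
            {
                "chrom": chrom,
                "pos": pos,
                "ref": ref,
                "alt": alt,
                "n_testable": snp.n_testable,
                "samples": ",".join(snp.samples),
                "total_ref": int(snp.ref_counts.sum()),
                "total_alt": int(snp.alt_counts.sum()),
                "mean_ref_fraction": float(snp.ref_counts.sum() / total) if total else None,
            }
        )
    write_report(
        rows,
        ["chrom", "pos", "ref", "alt", "n_testable", "samples",
         "total_ref", "total_alt", "mean_ref_fraction"],
        path,
        prov,
    )


def _write_meta(meta, prov, path) -> None:
    rows = [
        {
            "chrom": r.chrom, "pos": r.pos, "ref": r.ref, "alt": r.alt,
            "k": r.k, "fisher_x": r.fisher_x, "df": r.df,
            "combined_p": r.combined_p, "adj_p": r.adj_p,
            "is_ase": r.is_ase,
        }
        for r in meta
    ]
    write_report(
        rows,
        ["chrom", "pos", "ref", "alt", "k", "fisher_x", "df",
         "combined_p", "adj_p", "is_ase"],
        path,
        prov,
    )


def _write_mdfdr(mdfdr, prov, path) -> None:
    rows = []
    for r in mdfdr:
        for s, rc, ac, p, sig, d in zip(
            r.samples, r.ref_counts, r.alt_counts, r.pvalues, r.significant, r.directions
        ):
            rows.append(
                {
                    "chrom": r.chrom, "pos": r.pos, "ref": r.ref, "alt": r.alt,
                    "screen_p": r.screen_p, "screen_adj_p": r.screen_adj_p,
                    "selected": r.selected, "sample": s,
                    "ref_count": int(rc), "alt_count": int(ac),
                    "p": float(p), "significant": bool(sig), "direction": d,
                }
            )
    write_report(
        rows,
        ["chrom", "pos", "ref", "alt", "screen_p", "screen_adj_p", "selected",
         "sample", "ref_count", "alt_count", "p", "significant", "direction"],
        path,
        prov,
    )


def run(vcf_path, outdir, config: RunConfig | None = None) -> RunResult:
    """Execute the full detection flow and write all report files.

    Writes ``accounting.tsv``, ``informative.tsv``, and depending on the
    model choice ``meta_results.tsv`` and/or ``mdfdr_results.tsv`` plus
    ``frequency_summary.tsv``; a ``run_summary.tsv`` collects the scalar
    diagnostics (informative count, ASE counts, reference-allele ratio,
    direction concordance).
    """
    config = config or RunConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    prov = config.provenance()

    reader = read_vcf(vcf_path)
    samples = reader.samples
    logger.info("parsing %s (%d samples)", vcf_path, len(samples))
    informative, accounting = collect_informative(reader, samples, config.filters)
    if not accounting.check_partition():  # pragma: no cover - internal invariant
        raise AssertionError("filter accounting does not partition the input")
    logger.info("informative SNPs: %d of %d sites", accounting.informative, accounting.total)

    write_report(accounting.rows(), ["reason", "sites"], outdir / "accounting.tsv", prov)
    _write_informative(informative, prov, outdir / "informative.tsv")

    summary_rows: list[dict] = [
        {"quantity": "total_sites", "value": accounting.total},
        {"quantity": "informative_snps", "value": accounting.informative},
        {"quantity": "n_samples", "value": len(samples)},
    ]

    meta = None
    mdfdr = None
    if informative:
        ratio = reference_allele_ratio(informative)
        summary_rows.append({"quantity": "reference_allele_ratio_pct", "value": ratio})

        if config.model in ("meta", "both"):
            meta = run_meta_analysis(informative, alpha=config.alpha)
            _write_meta(meta, prov, outdir / "meta_results.tsv")
            n_ase = sum(r.is_ase for r in meta)
            summary_rows.append({"quantity": "ase_variants_meta", "value": n_ase})
            logger.info("meta-analysis ASE variants: %d", n_ase)

        if config.model in ("mdfdr", "both"):
            mdfdr = run_mdfdr(informative, alpha=config.alpha, screening=config.screening)
            _write_mdfdr(mdfdr, prov, outdir / "mdfdr_results.tsv")
            n_sel = sum(r.selected for r in mdfdr)
            summary_rows.append({"quantity": "ase_variants_mdfdr", "value": n_sel})

            _, freq_summary = ase_frequency(
                mdfdr,
                denominator=config.denominator,
                n_total_samples=len(samples),
            )
            write_report(
                freq_summary.rows(), ["bin", "count", "percent"],
                outdir / "frequency_summary.tsv", prov,
            )
            _, concord = direction_concordance(mdfdr)
            if concord is not None:
                summary_rows.append(
                    {"quantity": "direction_concordance_pct", "value": concord}
                )

    write_report(summary_rows, ["quantity", "value"], outdir / "run_summary.tsv", prov)
    return RunResult(
        samples=list(samples),
        informative=informative,
        accounting=accounting,
        meta=meta,
        mdfdr=mdfdr,
        outdir=outdir,
    )


def _read_keys(path: Path, ase_only: bool) -> set[str]:
    df = pd.read_csv(path, sep="\t", comment="#")
    if ase_only:
        df = df[df["is_ase"] == True]  # noqa: E712 - TSV booleans read as bool
    return set(
        f"{c}:{p}:{r}:{a}"
        for c, p, r, a in zip(df["chrom"], df["pos"], df["ref"], df["alt"])
    )


def combine_runs(
    run_dirs: Sequence[Path],
    outdir: Path,
    annotation: pd.DataFrame | None = None,
) -> dict:
    """Cross-run overlap counts and (optionally) global gene ASE scores.

    Each run directory must contain ``informative.tsv`` and
    ``meta_results.tsv``.  Writes ``overlap.tsv`` with informative- and
    ASE-set overlap counts for every subset of runs, and when an
    annotation table is given, ``gene_scores.tsv`` / ``global_gene_scores.tsv``.
    """
    from itertools import combinations

    from .summaries import gene_ase_scores, global_gene_scores, score_thresholds

    run_dirs = [Path(d) for d in run_dirs]
    if len(run_dirs) < 2:
        raise ValueError("combine needs at least two run directories")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    names = [d.name or str(d) for d in run_dirs]
    informative = {
        n: _read_keys(d / "informative.tsv", ase_only=False)
        for n, d in zip(names, run_dirs)
    }
    ase = {
        n: _read_keys(d / "meta_results.tsv", ase_only=True)
        for n, d in zip(names, run_dirs)
    }

    rows = []
    for size in range(1, len(names) + 1):
        for group in combinations(names, size):
            inf_common = set.intersection(*(informative[n] for n in group))
            ase_common = set.intersection(*(ase[n] for n in group))
            rows.append(
                {
                    "runs": "&".join(group),
                    "informative_overlap": len(inf_common),
                    "ase_overlap": len(ase_common),
                }
            )
    write_report(rows, ["runs", "informative_overlap", "ase_overlap"],
                 outdir / "overlap.tsv")

    out: dict = {"overlap": rows}
    if annotation is not None:
        scores = gene_ase_scores(annotation, informative, ase)
        global_scores = global_gene_scores(scores)
        scores.to_csv(outdir / "gene_scores.tsv", sep="\t", index=False)
        global_scores.to_csv(outdir / "global_gene_scores.tsv", sep="\t", index=False)
        out["thresholds"] = score_thresholds(global_scores)
    return out
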