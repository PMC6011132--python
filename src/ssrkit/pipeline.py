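"""Stage orchestration: marker discovery and marker evaluation bundles.

The stages add no computation of their own: discovery chains
mine -> classify -> primers over a FASTA; evaluation chains
popgen -> HWE -> LD over a GENEPOP file.  Every emitted file starts
with a provenance comment naming the config hash and seed.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from .config import RunConfig
from .equilibrium_tests import (
    genotypic_ld_test, hwe_test_locus, multiple_test_adjust,
)
from .io_formats import read_fasta, read_genepop
from .motif_classification import tabulate_frequencies
from .popgen_stats import summarize_locus, summaries_to_frame, summarize_panel
from .primer_screening import candidates_to_frame, screen_primer_pairs
from .ssr_mining import find_perfect_ssrs, loci_to_frame

logger = logging.getLogger("ssrkit")


def _write_tsv(frame: pd.DataFrame, path: Path, config: RunConfig,
               index: bool = False) -> None:
    with open(path, "w") as fh:
        fh.write(config.provenance_header())
        frame.to_csv(fh, sep="\t", index=index)


def read_report_tsv(path: str | Path, index_col=None) -> pd.DataFrame:
    """Read a pipeline TSV, skipping provenance comment lines."""
    return pd.read_csv(path, sep="\t", comment="#", index_col=index_col)


def run_marker_discovery(config: RunConfig, fasta: str | Path) -> dict[str, Path]:
    """mine -> classify -> primers; returns the bundle of written files."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    try:
        records = read_fasta(fasta)
    except ValueError as exc:
        raise RuntimeError(f"mine stage failed: {exc}") from exc

    loci = []
    for rec in records:
        loci.extend(find_perfect_ssrs(rec, config.thresholds))
    ssr_frame = loci_to_frame(loci)
    by_type, by_class = tabulate_frequencies(loci)

    rec_by_id = {r.id: r for r in records}
    primer_rows = []
    for locus in loci:
        outcome = screen_primer_pairs(
            rec_by_id[locus.seq_id], locus,
            constraints=config.primer_constraints,
            top_k=config.top_k_primers,
        )
        label = f"{locus.seq_id}:{locus.start}-{locus.end}({locus.motif})"
        primer_rows.append((locus.seq_id, label, outcome))
    primer_frame = candidates_to_frame(primer_rows)

    paths = {
        "ssr_tsv": out / "ssr_loci.tsv",
        "repeat_type_matrix": out / "frequency_by_repeat_type.tsv",
        "motif_class_matrix": out / "frequency_by_motif_class.tsv",
        "primer_tsv": out / "primer_candidates.tsv",
    }
    _write_tsv(ssr_frame, paths["ssr_tsv"], config)
    _write_tsv(by_type.table, paths["repeat_type_matrix"], config, index=True)
    _write_tsv(by_class.table, paths["motif_class_matrix"], config, index=True)
    _write_tsv(primer_frame, paths["primer_tsv"], config)
    logger.info(
        "discovery: %d sequences, %d SSR loci, %d primer candidates",
        len(records), len(loci), len(primer_frame),
    )
    return paths


def run_marker_evaluation(config: RunConfig, genepop: str | Path) -> dict[str, Path]:
    """popgen -> HWE -> LD over one GENEPOP file; returns written files."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    try:
        matrices = read_genepop(genepop)
    except ValueError as exc:
        raise RuntimeError(f"popgen stage failed: {exc}") from exc

    summaries = []
    hwe_rows = []
    for mat in matrices:
        for locus in mat.locus_names:
            s = summarize_locus(mat, locus)
            hwe = hwe_test_locus(mat, locus, seed=config.seed)
            summaries.append(
                type(s)(
                    **{
                        **s.__dict__,
                        "hwe_p": hwe.p_probability,
                        "hwe_deficit_p": hwe.p_deficit,
                        "hwe_excess_p": hwe.p_excess,
                    }
                )
            )
            hwe_rows.append(
                {
                    "locus": locus,
                    "population": mat.population_name,
                    "p_probability": hwe.p_probability,
                    "p_deficit": hwe.p_deficit,
                    "p_excess": hwe.p_excess,
                    "method": hwe.method,
                }
            )
    summary_frame = summaries_to_frame(summaries)
    hwe_frame = pd.DataFrame(hwe_rows)
    applicable = hwe_frame["p_probability"].notna()
    adjusted = pd.Series(float("nan"), index=hwe_frame.index)
    if applicable.any():
        adjusted[applicable] = multiple_test_adjust(
            list(hwe_frame.loc[applicable, "p_probability"]),
            method=config.adjust_method,
        )
    hwe_frame[f"p_adjusted_{config.adjust_method}"] = adjusted

    ld_rows = []
    for mat in matrices:
        loci = mat.locus_names
        for i in range(len(loci)):
            for j in range(i + 1, len(loci)):
                res = genotypic_ld_test(
                    mat, loci[i], loci[j],
                    n_permutations=config.n_permutations, seed=config.seed,
                )
                ld_rows.append(
                    {
                        "locus_a": loci[i],
                        "locus_b": loci[j],
                        "population": mat.population_name,
                        "G": res.statistic,
                        "p_value": res.p_value,
                        "applicable": res.applicable,
                    }
                )
    ld_frame = pd.DataFrame(ld_rows)
    if not ld_frame.empty:
        ok = ld_frame["p_value"].notna()
        adj = pd.Series(float("nan"), index=ld_frame.index)
        if ok.any():
            adj[ok] = multiple_test_adjust(
                list(ld_frame.loc[ok, "p_value"]), method=config.adjust_method
            )
        ld_frame[f"p_adjusted_{config.adjust_method}"] = adj

    _, means = summarize_panel(matrices)

    paths = {
        "summary_tsv": out / "locus_summaries.tsv",
        "panel_means_tsv": out / "panel_means.tsv",
        "hwe_tsv": out / "hwe_tests.tsv",
        "ld_tsv": out / "ld_tests.tsv",
    }
    _write_tsv(summary_frame, paths["summary_tsv"], config)
    _write_tsv(means, paths["panel_means_tsv"], config)
    _write_tsv(hwe_frame, paths["hwe_tsv"], config)
    _write_tsv(ld_frame, paths["ld_tsv"], config)
    logger.info(
        "evaluation: %d populations, %d locus summaries, %d LD pairs",
        len(matrices), len(summary_frame), len(ld_frame),
    )
    return paths
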