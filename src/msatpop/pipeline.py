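"""End-to-end orchestration: MLL -> diversity/HWE -> LD+FDR -> F_ST ->
admixture clustering with delta-K -> run merging -> DAPC.

Per-type layout: the reference type is analyzed on its full locus set,
the second type on cross-type loci only, and all between-type analyses
run on cross-type loci restricted to one representative per lineage.
Every stochastic stage receives its own seed derived deterministically
from the master seed, so a rerun with the same config reproduces all
numeric artifacts exactly.
"""

from __future__ import annotations

import itertools
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from . import clonality, differentiation, popgen
from .cluster import (
    MCMCConfig,
    align_and_merge,
    evanno,
    run_admixture,
    write_evanno_tsv,
    write_q_tsv,
)
from .dapc import dapc_fit, retain_pcs, write_dapc_tsv
from .genotype import GenotypeMatrix, read_genotype_table


@dataclass
class PipelineConfig:
    input_path: str
    dialect: str = "genalex"
    max_mismatch: int = 1
    min_compared: int = 5
    ld_n_perm: int = 1000
    fdr_q: float = 0.05
    fst_n_perm: int = 999
    k_min: int = 1
    k_max: int = 6
    cluster_iterations: int = 10
    burn_in: int = 5_000
    n_reps: int = 20_000
    dapc_pcs: int | str = "auto"
    seed: int = 1
    cross_type_loci: Sequence[str] | None = None  # None = all loci cross-type

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls(**(yaml.safe_load(Path(path).read_text()) or {}))


def stage_seeds(master_seed: int, names: Sequence[str]) -> dict[str, int]:
    """Deterministic per-stage 32-bit seeds from one master seed."""
    state = np.random.SeedSequence(master_seed).generate_state(len(names))
    return {name: int(v) for name, v in zip(names, state)}


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Run every stage, writing per-stage artifacts plus a summary report."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log: list[dict] = []
    report: dict = {"config": {k: v for k, v in asdict(config).items()}}
    seeds = stage_seeds(config.seed, ["ld", "fst", "cluster", "dapc"])
    report["stage_seeds"] = seeds

    def stage(name):
        class _Stage:
            def __enter__(self):
                self.t0 = time.perf_counter()
                return self

            def __exit__(self, exc_type, exc, tb):
                entry = {
                    "stage": name,
                    "seconds": round(time.perf_counter() - self.t0, 3),
                    "ok": exc is None,
                }
                if exc is not None:
                    entry["error"] = f"{type(exc).__name__}: {exc}"
                log.append(entry)
                _write_log(outdir, log)
                if exc is not None:
                    raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

        return _Stage()

    with stage("read"):
        matrix = read_genotype_table(config.input_path, config.dialect)
        types = matrix.mito_types
        ref_type = types[0]
        cross = (
            list(config.cross_type_loci)
            if config.cross_type_loci is not None
            else [l.locus_id for l in matrix.loci if l.cross_type]
        )

    # -- clonality per type ---------------------------------------------
    partitions: dict[str, clonality.MLLPartition] = {}
    collapsed: dict[str, GenotypeMatrix] = {}
    with stage("mll"):
        report["clonality"] = {}
        for t in types:
            loci = None if t == ref_type else cross
            sub = matrix.subset(mito_type=t, locus_ids=loci)
            part = clonality.assign_mlls(
                sub, max_mismatch=config.max_mismatch, min_compared=config.min_compared
            )
            partitions[t] = part
            collapsed[t] = clonality.collapse_to_mlls(sub, part)
            clonality.write_mll_tsv(part, outdir / f"mll_{_safe(t)}.tsv")
            report["clonality"][t] = {
                "N_MLL": part.n_mll,
                "N": part.n,
                "index": round(clonality.clonality_index(part), 3),
            }

    # -- per-locus diversity + HWE --------------------------------------
    with stage("stats"):
        report["locus_stats"] = {}
        for t in types:
            rows = []
            out_rows = []
            for lid in collapsed[t].locus_ids:
                st = popgen.summarize_locus(collapsed[t], lid)
                st = popgen.LocusStats(
                    locus_id=st.locus_id,
                    group=t,
                    n=st.n,
                    n_a=st.n_a,
                    h_e=st.h_e,
                    h_o=st.h_o,
                    f_is=st.f_is,
                )
                hwe = None
                if st.n_a >= 2 and st.n >= 5:
                    hwe = popgen.hwe_test(collapsed[t], lid)
                rows.append((st, hwe))
                out_rows.append(
                    {
                        "locus": lid,
                        "N_A": st.n_a,
                        "H_E": round(st.h_e, 3),
                        "H_O": round(st.h_o, 3),
                        "F_IS": round(st.f_is, 3) if st.f_is is not None else None,
                        "HWE_p": round(hwe.p_value, 4) if hwe else None,
                    }
                )
            popgen.write_locus_stats_tsv(rows, outdir / f"stats_{_safe(t)}.tsv")
            report["locus_stats"][t] = out_rows

    # -- linkage disequilibrium + FDR -----------------------------------
    with stage("ld"):
        report["ld"] = {}
        rng = np.random.default_rng(seeds["ld"])
        for t in types:
            results = []
            for la, lb in itertools.combinations(collapsed[t].locus_ids, 2):
                try:
                    results.append(
                        popgen.ld_test(
                            collapsed[t],
                            la,
                            lb,
                            n_perm=config.ld_n_perm,
                            seed=int(rng.integers(2**32)),
                        )
                    )
                except ValueError:
                    continue
            if results:
                flags = popgen.fdr_adjust(
                    [r.p_value for r in results], q=config.fdr_q
                )
                results = [
                    popgen.LDResult(
                        locus_a=r.locus_a,
                        locus_b=r.locus_b,
                        group=t,
                        g_statistic=r.g_statistic,
                        p_value=r.p_value,
                        n=r.n,
                        n_perm=r.n_perm,
                        significant_after_fdr=bool(f),
                    )
                    for r, f in zip(results, flags)
                ]
            popgen.write_ld_tsv(results, outdir / f"ld_{_safe(t)}.tsv")
            report["ld"][t] = {
                "n_pairs": len(results),
                "n_significant_after_fdr": sum(
                    bool(r.significant_after_fdr) for r in results
                ),
            }

    # -- between-type matrix (cross-type loci, MLL representatives) -----
    with stage("between_matrix"):
        reps = []
        for t in types:
            sub = matrix.subset(mito_type=t, locus_ids=cross)
            reps.extend(
                clonality.collapse_to_mlls(sub, partitions[t]).samples
            )
        between = GenotypeMatrix(
            loci=[l for l in matrix.loci if l.locus_id in set(cross)],
            samples=reps,
        )
        report["shared_alleles"] = None
        if len(types) == 2:
            n_shared, n_total = popgen.shared_allele_count(between, types[0], types[1])
            report["shared_alleles"] = {"n_shared": n_shared, "n_total": n_total}

    # -- F_ST -----------------------------------------------------------
    with stage("fst"):
        res = differentiation.fst_perm_test(
            between, n_perm=config.fst_n_perm, seed=seeds["fst"]
        )
        report["fst"] = {
            "fst": round(res.fst, 4),
            "p_value": res.p_value,
            "n_perm": res.n_perm,
        }
        (outdir / "fst.json").write_text(json.dumps(report["fst"], indent=1))

    # -- Bayesian clustering + Evanno + merge ---------------------------
    with stage("cluster"):
        rng = np.random.default_rng(seeds["cluster"])
        ln_pd_by_k: dict[int, list[float]] = {}
        runs_by_k: dict[int, list] = {}
        for k in range(config.k_min, config.k_max + 1):
            runs = [
                run_admixture(
                    between,
                    MCMCConfig(
                        k=k,
                        burn_in=config.burn_in,
                        n_reps=config.n_reps,
                        seed=int(rng.integers(2**32)),
                    ),
                )
                for _ in range(config.cluster_iterations)
            ]
            runs_by_k[k] = runs
            ln_pd_by_k[k] = [r.ln_pd for r in runs]
        summary = evanno(ln_pd_by_k) if len(ln_pd_by_k) >= 3 else None
        best_k = summary.best_k if summary is not None else max(
            ln_pd_by_k, key=lambda k: np.mean(ln_pd_by_k[k])
        )
        if summary is not None:
            write_evanno_tsv(summary, outdir / "evanno.tsv")
        merged = align_and_merge(runs_by_k[best_k])
        write_q_tsv(merged, between.sample_ids, outdir / f"q_merged_K{best_k}.tsv")
        report["cluster"] = {
            "ln_pd_by_k": {str(k): [round(v, 2) for v in vs] for k, vs in ln_pd_by_k.items()},
            "delta_k": {str(k): (None if np.isnan(d) else round(d, 2)) for k, d in zip(summary.ks, summary.delta_k)} if summary else None,
            "best_k": int(best_k),
            "alpha_warnings": [w for runs in runs_by_k.values() for r in runs for w in r.warnings],
        }

    # -- DAPC ------------------------------------------------------------
    with stage("dapc"):
        n_pcs = (
            retain_pcs(between.n_samples)
            if config.dapc_pcs == "auto"
            else int(config.dapc_pcs)
        )
        fit = dapc_fit(between, n_pcs=n_pcs)
        write_dapc_tsv(fit, outdir / "dapc.tsv")
        report["dapc"] = {
            "n_pcs": n_pcs,
            "n_axes": int(fit.coords.shape[1]),
            "warnings": fit.warnings,
        }

    with stage("report"):
        (outdir / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
        (outdir / "report.txt").write_text(format_report(report))
    return report


def _safe(label: str) -> str:
    return label.replace("/", "_").replace(" ", "_")


def _write_log(outdir: Path, log: list[dict]) -> None:
    (outdir / "pipeline_log.json").write_text(json.dumps(log, indent=1))


def format_report(report: dict) -> str:
    lines = ["msatpop pipeline report", "======================", ""]
    for t, c in report.get("clonality", {}).items():
        lines.append(
            f"{t}: N_MLL={c['N_MLL']}  N={c['N']}  N_MLL/N={c['index']:.3f}"
        )
    if report.get("shared_alleles"):
        sa = report["shared_alleles"]
        lines.append(
            f"shared alleles between types: {sa['n_shared']}/{sa['n_total']}"
        )
    if "fst" in report:
        f = report["fst"]
        lines.append(f"F_ST = {f['fst']:.4f}  (P = {f['p_value']:.4g}, {f['n_perm']} permutations)")
    if "ld" in report:
        for t, l in report["ld"].items():
            lines.append(
                f"LD ({t}): {l['n_significant_after_fdr']}/{l['n_pairs']} pairs significant after FDR"
            )
    if "cluster" in report:
        lines.append(f"best K by delta-K: {report['cluster']['best_k']}")
    if "dapc" in report:
        lines.append(
            f"DAPC: {report['dapc']['n_pcs']} PCs retained, {report['dapc']['n_axes']} discriminant axes"
        )
    return "\n".join(lines) + "\n"
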