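"""End-to-end orchestration: config-driven runs over real or synthetic panels.

A single YAML config (see :class:`PipelineConfig`) drives the full analysis
order: load or simulate a panel, PHI recombination tests on nuclear loci,
four-gamete filtering of flagged loci, per-locus haplotype networks,
per-population diversity and neutrality tables, pairwise Phi_ST matrices,
and optionally the ABC stage (reference table, model choice, error rates,
parameter estimation, unit scaling).  One master seed governs every
stochastic stage through the documented counter scheme; every output file
is checksummed into ``manifest.tsv``.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import yaml

from . import abc as abc_mod
from . import network as net_mod
from . import popgen, recomb
from .data_model import (
    LocusSpec,
    SequencePanel,
    collapse_haplotypes,
    read_panel,
    write_panel,
    write_stats_table,
)
from .synthetic import (
    MULTILOCUS_SAMPLE_SIZES,
    REGION_OF_POP,
    SCENARIO1_REFERENCE_PARAMS,
    MergeEvent,
    ParameterDraw,
    PriorSpec,
    SamplingDesign,
    ScenarioSpec,
    builtin_scenarios,
    child_rng,
    default_design,
    default_loci,
    draw_parameters,
    simulate_dataset,
)

logger = logging.getLogger("phyloabc")

__all__ = ["PipelineConfig", "run_pipeline", "make_fixture", "scenario_from_dict"]


def scenario_from_dict(d: Mapping[str, Any]) -> ScenarioSpec:
    """Build a scenario from its structured-config form.

    Expected keys: ``id``, ``populations``, ``events`` (list of
    ``[time_param, source, dest]``), ``size_param`` (branch -> name,
    default ``N_<branch>``), ``priors`` (param -> [lower, upper]),
    ``constraints`` (list of ``[earlier, later]``).
    """
    pops = tuple(d["populations"])
    events = tuple(MergeEvent(*e) for e in d["events"])
    size_param = dict(d.get("size_param") or {p: f"N_{p}" for p in pops})
    priors = {k: PriorSpec(float(v[0]), float(v[1])) for k, v in d["priors"].items()}
    return ScenarioSpec(
        id=d["id"],
        populations=pops,
        events=events,
        size_param=size_param,
        priors=priors,
        ordering_constraints=tuple((a, b) for a, b in d.get("constraints", [])),
        description=d.get("description", ""),
    )


@dataclass
class PipelineConfig:
    """Parsed pipeline configuration; see ``from_yaml``."""

    panel: Mapping[str, Any] | None = None  # fasta paths + metadata
    synthetic: Mapping[str, Any] | None = None  # scenario/params/seed block
    loci: list[LocusSpec] = field(default_factory=default_loci)
    stats: Mapping[str, Any] = field(default_factory=dict)
    recombination: Mapping[str, Any] = field(default_factory=dict)
    networks: bool = True
    abc: Mapping[str, Any] | None = None
    scaling: Mapping[str, Any] = field(default_factory=dict)
    master_seed: int = 0

    @classmethod
    def from_yaml(cls, path: str, seed: int | None = None) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        loci = (
            [
                LocusSpec(
                    l["name"],
                    int(l["length_bp"]),
                    float(l.get("inheritance_scalar", 1.0)),
                    float(l.get("mu_site_gen", 1e-9)),
                    int(l.get("copies_per_individual", 2)),
                )
                for l in raw["loci"]
            ]
            if "loci" in raw
            else default_loci()
        )
        return cls(
            panel=raw.get("panel"),
            synthetic=raw.get("synthetic"),
            loci=loci,
            stats=raw.get("stats", {}),
            recombination=raw.get("recombination", {}),
            networks=raw.get("networks", True),
            abc=raw.get("abc"),
            scaling=raw.get("scaling", {}),
            master_seed=seed if seed is not None else int(raw.get("seed", 0)),
        )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _load_or_simulate(cfg: PipelineConfig) -> SequencePanel:
    if cfg.panel:
        logger.info("loading panel from FASTA")
        return read_panel(cfg.panel["fasta"], cfg.panel["metadata"], cfg.loci)
    if cfg.synthetic is None:
        raise ValueError("config needs either a 'panel' or a 'synthetic' block")
    blk = cfg.synthetic
    scenarios = {s.id: s for s in builtin_scenarios()}
    sid = blk.get("scenario", "scenario1")
    if isinstance(sid, Mapping):
        sc = scenario_from_dict(sid)
    else:
        sc = scenarios[sid]
    seed = int(blk.get("seed", cfg.master_seed))
    if "parameters" in blk:
        draw = ParameterDraw(sc.id, dict(blk["parameters"]), seed)
    else:
        draw = draw_parameters(sc, child_rng(seed, 0))
        logger.info("prior-drawn parameters: %s", draw.values)
    design = SamplingDesign(dict(blk.get("sample_sizes", MULTILOCUS_SAMPLE_SIZES)))
    logger.info("simulating panel under %s (seed %d)", sc.id, seed)
    return simulate_dataset(sc, draw, cfg.loci, design, rng_seed=seed)


def run_pipeline(cfg: PipelineConfig, out_dir: str) -> Path:
    """Run all configured stages; returns the artifact directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: list[Path] = []

    panel = _load_or_simulate(cfg)
    fasta_paths = {sp.name: str(out / f"panel_{sp.name}.fasta") for sp in panel.loci}
    write_panel(panel, fasta_paths, str(out / "panel_metadata.tsv"))
    artifacts += [Path(p) for p in fasta_paths.values()] + [out / "panel_metadata.tsv"]

    # recombination screen on nuclear loci
    rec_cfg = cfg.recombination
    phi_rows = []
    filter_loci = list(rec_cfg.get("filter_loci", []))
    for sp in panel.loci:
        if sp.is_mtdna:
            continue
        recs = panel.records_for(sp.name)
        res = recomb.phi_test(
            recs,
            window_w=int(rec_cfg.get("window_w", 100)),
            n_perms=int(rec_cfg.get("n_perms", 1000)),
            rng_seed=child_rng(cfg.master_seed, 1_000),
        )
        phi_rows.append(
            {
                "locus": sp.name,
                "phi_w": res.phi_w,
                "p_value": res.p_value,
                "n_informative_sites": res.n_informative_sites,
                "applicable": res.applicable,
            }
        )
        if rec_cfg.get("auto_filter") and res.applicable and res.p_value < 0.05:
            filter_loci.append(sp.name)
    if phi_rows:
        write_stats_table(phi_rows, str(out / "phi_test.tsv"))
        artifacts.append(out / "phi_test.tsv")

    filtered = panel
    if filter_loci:
        new_records = dict(panel.records)
        new_loci = []
        filt_rows = []
        for sp in panel.loci:
            if sp.name in filter_loci:
                rep = recomb.filter_recombinant_sites(panel.records_for(sp.name))
                new_records[sp.name] = rep.retained_records
                new_len = sp.length_bp - len(rep.removed_site_positions)
                new_loci.append(
                    LocusSpec(sp.name, new_len, sp.inheritance_scalar, sp.mu_site_gen,
                              sp.copies_per_individual)
                )
                filt_rows.append(
                    {
                        "locus": sp.name,
                        "removed_positions": ",".join(map(str, rep.removed_site_positions)) or "NA",
                        "violating_pairs_before": rep.violating_pairs_before,
                        "violating_pairs_after": rep.violating_pairs_after,
                    }
                )
                logger.info("%s: removed %d recombinant sites", sp.name,
                            len(rep.removed_site_positions))
            else:
                new_loci.append(sp)
        filtered = SequencePanel(loci=new_loci, records=new_records)
        write_stats_table(filt_rows, str(out / "four_gamete_filter.tsv"))
        artifacts.append(out / "four_gamete_filter.tsv")

    # haplotype networks
    if cfg.networks:
        for sp in filtered.loci:
            haps = collapse_haplotypes(filtered, sp.name)
            g = net_mod.build_msn(haps)
            gp = out / f"network_{sp.name}.graphml"
            ep = out / f"network_{sp.name}_edges.tsv"
            net_mod.export_network(g, str(gp), str(ep))
            artifacts += [gp, ep]

    # diversity / neutrality tables
    st_cfg = cfg.stats
    n_sims = int(st_cfg.get("n_sims", 1000))
    pops = filtered.populations()
    div_rows = []
    for sp in filtered.loci:
        for pop in pops:
            recs = filtered.records_for(sp.name, pop)
            if len(recs) < 2:
                continue
            mat = popgen.records_matrix(recs)
            st = popgen.diversity(mat)
            row = {
                "locus": sp.name, "population": pop, "n": st.n, "H": st.H,
                "h": st.h, "S": st.S, "k": st.k, "pi": st.pi,
            }
            for label, key in [("D", "D"), ("Fs", "Fs"), ("R2", "r2")]:
                fn = {"D": popgen.tajima_d, "Fs": popgen.fu_fs, "r2": popgen.r2}[key]
                val = fn(mat)
                if math.isnan(val):
                    row[label], row[f"p_{label}"] = math.nan, math.nan
                else:
                    _, p = popgen.significance(
                        mat, key, n_sims=n_sims,
                        rng_seed=child_rng(cfg.master_seed, 2_000),
                    )
                    row[label], row[f"p_{label}"] = val, p
            div_rows.append(row)
    write_stats_table(div_rows, str(out / "diversity.tsv"))
    artifacts.append(out / "diversity.tsv")

    # pairwise Phi_ST matrices
    n_perms = int(st_cfg.get("n_perms", 1000))
    fst_rows = []
    for sp in filtered.loci:
        mats = {p: popgen.records_matrix(filtered.records_for(sp.name, p)) for p in pops}
        for i, pa in enumerate(pops):
            for pb in pops[i + 1:]:
                if mats[pa].shape[0] < 2 or mats[pb].shape[0] < 2:
                    continue
                res = popgen.pairwise_phi_st(
                    mats[pa], mats[pb], n_perms=n_perms,
                    rng_seed=child_rng(cfg.master_seed, 3_000),
                )
                fst_rows.append(
                    {"locus": sp.name, "pop_a": pa, "pop_b": pb,
                     "phi_st": res.phi_st, "p_value": res.p_value}
                )
    write_stats_table(fst_rows, str(out / "phi_st.tsv"))
    artifacts.append(out / "phi_st.tsv")

    # ABC stage
    if cfg.abc is not None:
        ab = cfg.abc
        scenarios = builtin_scenarios()
        if "scenarios" in ab:
            scenarios = [scenario_from_dict(s) for s in ab["scenarios"]]
        design = SamplingDesign(
            dict(ab.get("sample_sizes")) if ab.get("sample_sizes")
            else {p: len({r.individual for r in filtered.records_for(filtered.loci[0].name, p)})
                  for p in pops}
        )
        n_per = int(ab.get("n_per_scenario", 10_000))
        n_retain = int(ab.get("n_retain", 500))
        logger.info("building reference table: %d scenarios x %d", len(scenarios), n_per)
        table = abc_mod.build_reference_table(
            scenarios, filtered.loci, design, n_per, master_seed=cfg.master_seed
        )
        observed = abc_mod.summarize_panel(filtered, populations=list(scenarios[0].populations))
        rej = abc_mod.reject(table, observed, n_retain)
        mc = abc_mod.model_choice(
            table, rej, observed,
            n_boot=int(ab.get("n_boot", 200)),
            rng_seed=child_rng(cfg.master_seed, 4_000),
        )
        result: dict[str, Any] = {
            "scenario_probabilities": dict(zip(mc.scenario_ids, mc.probabilities.tolist())),
            "ci_lower": dict(zip(mc.scenario_ids, mc.ci_lower.tolist())),
            "ci_upper": dict(zip(mc.scenario_ids, mc.ci_upper.tolist())),
            "selected": mc.selected,
        }
        if ab.get("error_rates"):
            er = abc_mod.error_rates(
                table, scenarios, filtered.loci, design, focal=mc.selected,
                n_pods=int(ab.get("n_pods", 500)),
                n_retain=n_retain, rng_seed=cfg.master_seed + 17,
            )
            result["error_rates"] = {
                "focal": er.focal,
                "false_positive_rate": er.false_positive_rate,
                "false_negative_rate": er.false_negative_rate,
            }
        sel = next(s for s in scenarios if s.id == mc.selected)
        post = abc_mod.estimate_parameters(
            table, observed, sel,
            retain_fraction=float(ab.get("retain_fraction", 0.01)),
        )
        scal = abc_mod.ScalingConfig(
            divergence_rate_per_myr=float(cfg.scaling.get("divergence_rate_per_myr", 0.01)),
            generation_time_years=float(cfg.scaling.get("generation_time_years", 1.0)),
        )
        est = {}
        for j, pn in enumerate(post.param_names):
            entry = {
                "mode": post.modes[j],
                "ci_2.5": post.ci_lower[j],
                "ci_97.5": post.ci_upper[j],
            }
            if pn.startswith("t_"):
                entry["mode_years"] = abc_mod.scale_units(
                    post.modes[j], "generations_to_years", filtered.loci[0], scal
                )
            est[pn] = entry
        result["parameter_estimates"] = est
        result["adjusted"] = post.adjusted
        with open(out / "abc_results.json", "w") as fh:
            json.dump(result, fh, indent=2)
        artifacts.append(out / "abc_results.json")

    manifest = [
        {"file": p.name, "sha256": _sha256(p)} for p in sorted(artifacts, key=lambda p: p.name)
    ]
    write_stats_table(manifest, str(out / "manifest.tsv"))
    logger.info("wrote %d artifacts to %s", len(artifacts), out)
    return out


# ---------------------------------------------------------------------------
# deterministic test fixtures


def make_fixture(name: str, seed: int, out_dir: str) -> list[Path]:
    """Write a small deterministic fixture; returns the files created.

    ``tiny_panel``: the 4-sequence, 2-site mtDNA alignment whose Tajima's D
    is about 0.59.  ``recombinant_locus``: an alignment containing the two
    reciprocal single-crossover products of two divergent haplotypes, which
    fails the four-gamete test.  ``scenario1_pods``: ten panels simulated
    under the single-colonization scenario at its reference parameter point.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files: list[Path] = []
    if name == "tiny_panel":
        loci = [LocusSpec("TINY", 2, 0.25, 1e-8, 1)]
        seqs = {"i1": "AA", "i2": "AA", "i3": "GG", "i4": "AG"}
        fa = out / "tiny_panel.fasta"
        with open(fa, "w") as fh:
            for ind, s in seqs.items():
                fh.write(f">{ind}|0\n{s}\n")
        meta = out / "tiny_panel_metadata.tsv"
        with open(meta, "w") as fh:
            fh.write("individual\tpopulation\tregion\n")
            for ind in seqs:
                fh.write(f"{ind}\tP1\tNWP\n")
        files = [fa, meta]
    elif name == "recombinant_locus":
        rng = child_rng(seed, 0)
        L = 60
        a = ["A"] * L
        b = ["A"] * L
        for pos in rng.choice(L // 2, size=6, replace=False):
            b[int(pos)] = "G"
        for pos in rng.choice(np.arange(L // 2, L), size=6, replace=False):
            b[int(pos)] = "G"
        cross = L // 2
        r1 = a[:cross] + b[cross:]
        r2 = b[:cross] + a[cross:]
        fa = out / "recombinant_locus.fasta"
        with open(fa, "w") as fh:
            for i, s in enumerate([a, a, b, b, r1, r1, r2, r2]):
                fh.write(f">i{i + 1}|0\n{''.join(s)}\n")
        files = [fa]
    elif name == "scenario1_pods":
        sc = builtin_scenarios()[0]
        loci = default_loci()
        design = default_design()
        draw = ParameterDraw(sc.id, dict(SCENARIO1_REFERENCE_PARAMS), seed)
        for i in range(10):
            panel = simulate_dataset(sc, draw, loci, design, rng_seed=int(
                child_rng(seed, i).integers(0, 2**31)))
            paths = {sp.name: str(out / f"pod{i:02d}_{sp.name}.fasta") for sp in loci}
            write_panel(panel, paths, str(out / f"pod{i:02d}_metadata.tsv"))
            files += [Path(p) for p in paths.values()] + [out / f"pod{i:02d}_metadata.tsv"]
    else:
        raise ValueError(f"unknown fixture {name!r}")
    return files
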