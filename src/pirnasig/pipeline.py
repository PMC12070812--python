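"""End-to-end orchestration of the synthetic piRNA study.

A :class:`PipelineConfig` carries every stage parameter (defaults encode
the analysis settings used throughout: 30-nt 3' trim, 23-28 nt piRNA
window, >=5-count species filter, Z windows, p_adj <= 0.05 /
|log2FC| >= 0.58 DE cutoffs, GI > 2, quadrant cutoffs 3.7 / 1.0, 3-fold IP
rule). ``run_pipeline`` executes simulate -> collapse -> align -> profile
-> signatures -> quantify -> DE -> GI / quadrant / concomitant / IP and
writes TSV/JSON outputs plus a manifest of file digests; ``generate_report``
collates them into one JSON + a human-readable summary.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from ._utils import child_rng
from .io import write_fasta, write_tsv
from .mapping import PanelIndex, align_species, build_end_profiles, size_filter, trim_and_collapse
from .quantify import TECountTable, differential_expression, fold_change_calls, quantify_te, split_strand_fc
from .signatures import histogram_frame, nucleotide_bias, phasing_signature, pingpong_signature
from .simulate import (
    ConditionEffect,
    LibrarySimSpec,
    TEPanelSpec,
    apply_condition_effect,
    generate_te_panel,
    simulate_count_table,
    simulate_ip_libraries,
    simulate_library,
)
from .interactions import concomitant_grouping, gi_scores, ip_group_assignment, ip_group_overlap, quadrant_analysis

log = logging.getLogger("pirnasig")

ALL_STAGES = ("simulate", "signatures", "quantify", "de", "interactions", "ip", "report")


@dataclass
class GenotypeSpec:
    """One genotype of the simulated cross, with its pathway suppression."""

    genotype: str
    role: str = "other"  # control / single / double / other
    pingpong_scale: float = 1.0
    phased_scale: float = 1.0
    sense_scale: float = 1.0
    antisense_scale: float = 1.0


def _default_genotypes() -> list[GenotypeSpec]:
    # WT, a ping-pong-pathway knockdown, a milder mutant biased against
    # sense reads, and their double mutant.
    return [
        GenotypeSpec("WT", "control"),
        GenotypeSpec("aubKD", "single", pingpong_scale=0.05, phased_scale=0.5),
        GenotypeSpec("Top3bKO", "single", pingpong_scale=0.7, phased_scale=0.9, sense_scale=0.7),
        GenotypeSpec(
            "Top3bKO_aubKD", "double", pingpong_scale=0.005, phased_scale=0.3, sense_scale=0.5
        ),
    ]


@dataclass
class PipelineConfig:
    outdir: str = "pirnasig_run"
    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES
    # panel
    n_te: int = 50
    te_length_range: tuple[int, int] = (500, 5000)
    repeat_fraction: float = 0.1
    # libraries
    n_reads: int = 30_000
    pingpong_fraction: float = 0.3
    phased_fraction: float = 0.3
    u1_prob: float = 0.78
    a10_prob: float = 0.65
    copies_mean: float = 8.0
    n_reps: int = 3
    genotypes: list[GenotypeSpec] = field(default_factory=_default_genotypes)
    # read prep
    trim_mode: str = "fixed3p"
    trim_len: int = 30
    adapter_seq: str | None = None
    min_read_len: int = 15
    size_lo: int = 23
    size_hi: int = 28
    min_species_count: int = 5
    # DE
    de_alpha: float = 0.05
    de_lfc_theta: float = 0.58
    pirna_fc_cutoff: float = 2.0
    # RNA layer / interactions
    rna_n_reps: int = 3
    rna_dispersion: float = 0.05
    n_desilenced: int = 10
    desilenced_fc: float = 4.0
    gi_cutoff: float = 2.0
    quadrant_len_cut: float = 3.7
    quadrant_expr_cut: float = 1.0
    ip_fold: float = 3.0
    ip_enrichment: float = 10.0

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        """Load from TOML, JSON, or YAML; unknown keys are rejected."""
        path = Path(path)
        text = path.read_text()
        if path.suffix == ".toml":
            import tomllib

            data = tomllib.loads(text)
        elif path.suffix == ".json":
            data = json.loads(text)
        else:
            import yaml

            data = yaml.safe_load(text)
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "genotypes" in data:
            data = dict(data)
            data["genotypes"] = [
                g if isinstance(g, GenotypeSpec) else GenotypeSpec(**g) for g in data["genotypes"]
            ]
        if "stages" in data:
            data["stages"] = tuple(data["stages"])
        if "te_length_range" in data:
            data["te_length_range"] = tuple(data["te_length_range"])
        return cls(**data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["stages"] = list(self.stages)
        d["te_length_range"] = list(self.te_length_range)
        return d

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    def validate(self) -> None:
        bad = set(self.stages) - set(ALL_STAGES)
        if bad:
            raise ValueError(f"unknown stages: {sorted(bad)}")
        if self.size_lo > self.size_hi:
            raise ValueError("size window inverted")
        roles = [g.role for g in self.genotypes]
        if roles.count("control") != 1:
            raise ValueError("exactly one control genotype is required")


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _roles(config: PipelineConfig):
    control = next(g for g in config.genotypes if g.role == "control")
    singles = [g for g in config.genotypes if g.role == "single"]
    doubles = [g for g in config.genotypes if g.role == "double"]
    return control, singles, doubles


def _build_te_fc_maps(
    config: PipelineConfig, panel, rng, rpkm: pd.Series
) -> dict[str, dict[str, float]]:
    """RNA-layer fold changes: each mutant de-silences n TEs, biased toward
    long and highly expressed ones; the double mutant's FC is 3x the sum of
    the singles' FCs on a shared core subset (a strong positive genetic
    interaction)."""
    control, singles, doubles = _roles(config)
    lengths = np.array([te.length for te in panel], dtype=float)
    expr = rpkm.reindex([te.id for te in panel]).to_numpy() + 1e-9
    p = lengths * expr
    p = p / p.sum()  # long, highly expressed TEs are hit preferentially
    n = min(config.n_desilenced, len(panel))
    core = rng.choice(len(panel), size=n, replace=False, p=p)
    maps: dict[str, dict[str, float]] = {control.genotype: {}}
    for g in singles:
        fc = {panel[i].id: config.desilenced_fc * float(rng.uniform(0.8, 1.2)) for i in core}
        maps[g.genotype] = fc
    for g in doubles:
        fc = {}
        for i in core:
            te = panel[i].id
            s = sum(maps[s_g.genotype].get(te, 1.0) for s_g in singles) or 2.0
            fc[te] = 3.0 * s
        maps[g.genotype] = fc
    return maps


def run_pipeline(config: PipelineConfig, progress: bool = False) -> dict:
    """Execute the configured stages; return the run manifest (also written
    to <outdir>/manifest.json)."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "stages": {},
        "outputs": {},
    }
    config.write(outdir / "config.json")
    log.info("run started: outdir=%s seed=%d", outdir, config.seed)

    rng = child_rng(config.seed, 10)
    panel = generate_te_panel(
        TEPanelSpec(config.n_te, config.te_length_range, config.repeat_fraction, seed=config.seed)
    )
    write_fasta(outdir / "panel.fasta", [(te.id, te.sequence) for te in panel])
    ref_lengths = {te.id: te.length for te in panel}
    index = PanelIndex(panel)

    base_spec = LibrarySimSpec(
        n_reads=config.n_reads,
        pingpong_fraction=config.pingpong_fraction,
        phased_fraction=config.phased_fraction,
        u1_prob=config.u1_prob,
        a10_prob=config.a10_prob,
        copies_mean=config.copies_mean,
        seed=config.seed,
    )

    samples: list[dict] = []
    per_sample: dict[str, dict] = {}
    lib_no = 0
    for g in config.genotypes:
        effect = ConditionEffect(
            g.genotype,
            pingpong_scale=g.pingpong_scale,
            phased_scale=g.phased_scale,
            sense_scale=g.sense_scale,
            antisense_scale=g.antisense_scale,
        )
        spec = apply_condition_effect(base_spec, effect)
        for rep in range(1, config.n_reps + 1):
            lib_no += 1
            sample = f"{g.genotype}_rep{rep}"
            lib_spec = dataclasses.replace(spec, seed=(config.seed * 1000 + lib_no) % (2**31))
            reads, gt = simulate_library(panel, lib_spec)
            species = trim_and_collapse(
                ((seq, int(c)) for _, seq, c in reads.itertuples(index=False)),
                mode="fixed3p",
                trim_len=0,  # simulated reads carry no adapter
                min_len=config.min_read_len,
            )
            kept, hist = size_filter(species, config.size_lo, config.size_hi)
            alignments = align_species(kept, panel, index=index)
            per_sample[sample] = {
                "reads": reads,
                "ground_truth": gt,
                "species": kept,
                "size_hist": hist,
                "alignments": alignments,
                "genotype": g.genotype,
            }
            samples.append({"sample": sample, "genotype": g.genotype, "replicate": rep})
            if progress:
                log.info("simulated+aligned %s (%d species)", sample, len(kept))
    sheet = pd.DataFrame(samples)
    write_tsv(outdir / "samples.tsv", sheet)
    sizes = pd.DataFrame({s: d["size_hist"] for s, d in per_sample.items()})
    sizes.index.name = "length"
    write_tsv(outdir / "size_histograms.tsv", sizes.reset_index())
    manifest["stages"]["simulate"] = {"n_samples": len(samples), "n_te": len(panel)}

    # --- signatures --------------------------------------------------------
    if "signatures" in config.stages:
        sig_rows, bias_rows = [], []
        for sample, d in per_sample.items():
            profiles = build_end_profiles(d["alignments"], ref_lengths)
            pp_hist, z10 = pingpong_signature(profiles)
            h35, h55, z0 = phasing_signature(profiles)
            sig_rows.append(
                {
                    "sample": sample,
                    "genotype": d["genotype"],
                    "z10": z10.value,
                    "z10_defined": z10.defined,
                    "z0": z0.value,
                    "z0_defined": z0.defined,
                }
            )
            d["pp_hist"], d["h35"], d["h55"] = pp_hist, h35, h55
            for position, nt, name in ((1, "T", "1U"), (10, "A", "10A")):
                res = nucleotide_bias(
                    d["species"], d["alignments"], position, nt, config.min_species_count
                )
                for scope, r in res.items():
                    bias_rows.append(
                        {
                            "sample": sample,
                            "signature": name,
                            "scope": scope,
                            "n_eligible": r.n_eligible,
                            "n_hit": r.n_hit,
                            "percent": r.percent,
                        }
                    )
            write_tsv(outdir / f"hist_pingpong_{sample}.tsv", histogram_frame(pp_hist))
            write_tsv(outdir / f"hist_phase3p5p_{sample}.tsv", histogram_frame(h35))
            write_tsv(outdir / f"hist_phase5p5p_{sample}.tsv", histogram_frame(h55))
        write_tsv(outdir / "signature_scores.tsv", pd.DataFrame(sig_rows))
        write_tsv(outdir / "nucleotide_bias.tsv", pd.DataFrame(bias_rows))
        manifest["stages"]["signatures"] = {"n_libraries": len(sig_rows)}

    # --- quantify ----------------------------------------------------------
    control, singles, doubles = _roles(config)
    if "quantify" in config.stages or "de" in config.stages:
        cols = {}
        for sample, d in per_sample.items():
            cols[sample] = quantify_te(
                d["alignments"],
                panel,
                per_strand=True,
                min_species_count=config.min_species_count,
                species=d["species"],
            )
        pirna_counts = pd.DataFrame(cols)
        pirna_counts.index.name = "feature"
        write_tsv(outdir / "pirna_counts.tsv", pirna_counts.reset_index())
        lengths = pd.Series(ref_lengths)
        table = TECountTable(
            counts=pirna_counts,
            lengths=lengths,
            sample_genotype={s["sample"]: s["genotype"] for s in samples},
        )
        write_tsv(outdir / "pirna_pkb.tsv", table.pkb().reset_index())
        manifest["stages"]["quantify"] = {"n_features": len(pirna_counts)}

    # --- piRNA-level DE (2-fold) ------------------------------------------
    strand_joins = {}
    if "de" in config.stages:
        ctrl_samples = table.samples_of(control.genotype)
        for g in config.genotypes:
            if g.role == "control":
                continue
            mut_samples = table.samples_of(g.genotype)
            # simulated libraries are depth-matched, so the 2-fold strand
            # comparisons run on raw apportioned counts: normalizing within
            # a single-strand table would absorb a uniform strand suppression
            sense = fold_change_calls(
                pirna_counts[pirna_counts.index.str.endswith(":+")],
                ctrl_samples,
                mut_samples,
                cutoff=config.pirna_fc_cutoff,
                normalize=False,
            )
            anti = fold_change_calls(
                pirna_counts[pirna_counts.index.str.endswith(":-")],
                ctrl_samples,
                mut_samples,
                cutoff=config.pirna_fc_cutoff,
                normalize=False,
            )
            both_counts = pirna_counts.copy()
            both_counts.index = both_counts.index.str.replace(r":[+-]$", "", regex=True)
            both = fold_change_calls(
                both_counts.groupby(level=0).sum(),
                ctrl_samples,
                mut_samples,
                cutoff=config.pirna_fc_cutoff,
                normalize=False,
            )
            joined = split_strand_fc(sense, anti, both)
            strand_joins[g.genotype] = joined
            write_tsv(outdir / f"pirna_strand_fc_{g.genotype}.tsv", joined)
        manifest["stages"]["de"] = {"comparisons": [g for g in strand_joins]}

    # --- RNA layer: DE, GI, quadrant, concomitant --------------------------
    if "interactions" in config.stages:
        # probe the baseline expression first (the rpkm draw is a pure
        # function of the seed, so the full table below shares it)
        probe = simulate_count_table(
            panel, [ConditionEffect(control.genotype)], n_reps=config.rna_n_reps,
            dispersion=config.rna_dispersion, seed=config.seed + 7,
        )
        baseline_rpkm = probe.rpkm().mean(axis=1)
        fc_maps = _build_te_fc_maps(config, panel, rng, baseline_rpkm)
        effects = [
            ConditionEffect(g.genotype, te_fc_map=fc_maps.get(g.genotype, {}))
            for g in config.genotypes
        ]
        rna = simulate_count_table(
            panel,
            effects,
            n_reps=config.rna_n_reps,
            dispersion=config.rna_dispersion,
            seed=config.seed + 7,
        )
        write_tsv(outdir / "rna_counts.tsv", rna.counts.reset_index())
        ctrl = rna.samples_of(control.genotype)
        de_tables, linear_fc, desil_sets = {}, {}, {}
        for g in config.genotypes:
            if g.role == "control":
                continue
            de = differential_expression(
                rna.counts,
                ctrl,
                rna.samples_of(g.genotype),
                alpha=config.de_alpha,
                lfc_theta=config.de_lfc_theta,
            )
            de_tables[g.genotype] = de
            linear_fc[g.genotype] = pd.Series(
                2.0 ** de["log2fc"].to_numpy(), index=de["feature"]
            )
            desil_sets[g.genotype] = set(de.loc[de["call"] == "up", "feature"])
            write_tsv(outdir / f"rna_de_{g.genotype}.tsv", de)

        gi_out = {}
        if doubles and len(singles) >= 2:
            dg = doubles[0].genotype
            s1, s2 = singles[0].genotype, singles[1].genotype
            records, summary = gi_scores(
                linear_fc[dg],
                linear_fc[s1],
                linear_fc[s2],
                strong_cutoff=config.gi_cutoff,
                desilenced=desil_sets[dg],
            )
            write_tsv(outdir / "gi_scores.tsv", records)
            gi_out = summary
        # quadrant analysis on the most de-silencing mutant vs control rpkm
        target = doubles[0].genotype if doubles else (singles[0].genotype if singles else None)
        quad_out = {}
        if target is not None:
            rpkm_ctrl = rna.rpkm()[ctrl].mean(axis=1)
            q_records, q_summary = quadrant_analysis(
                rna.lengths,
                rpkm_ctrl,
                desil_sets[target],
                config.quadrant_len_cut,
                config.quadrant_expr_cut,
            )
            write_tsv(outdir / "quadrants.tsv", q_records)
            write_tsv(outdir / "quadrant_summary.tsv", q_summary)
            quad_out = q_summary.to_dict(orient="records")
        conc_out = {}
        if strand_joins:
            g0 = next(iter(strand_joins))
            joined = strand_joins[g0]
            reduced = set(joined.loc[joined["call_both"] == "down", "te_id"])
            c_records, c_summary = concomitant_grouping(joined, reduced, config.pirna_fc_cutoff)
            write_tsv(outdir / "concomitant_groups.tsv", c_records)
            conc_out = {"comparison": g0, **c_summary}
        (outdir / "interaction_summary.json").write_text(
            json.dumps({"gi": gi_out, "quadrants": quad_out, "concomitant": conc_out}, indent=2, default=str)
        )
        manifest["stages"]["interactions"] = {"gi": gi_out}

    # --- IP groups ---------------------------------------------------------
    if "ip" in config.stages:
        first_ctrl = f"{control.genotype}_rep1"
        d = per_sample[first_ctrl]
        ip_counts = simulate_ip_libraries(
            d["reads"], d["ground_truth"], enrichment=config.ip_enrichment, seed=config.seed + 11
        )
        assignment = ip_group_assignment(ip_counts, fold=config.ip_fold)
        write_tsv(outdir / "ip_assignments.tsv", assignment)
        overlap = ip_group_overlap(d["species"], assignment)
        (outdir / "ip_overlap.json").write_text(json.dumps(overlap, indent=2))
        manifest["stages"]["ip"] = overlap

    # --- manifest & report -------------------------------------------------
    manifest["runtime_s"] = round(time.time() - t0, 2)
    for f in sorted(outdir.iterdir()):
        if f.is_file() and f.name != "manifest.json":
            manifest["outputs"][f.name] = _digest(f)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    if "report" in config.stages:
        generate_report(outdir)
    log.info("run finished in %.1fs", manifest["runtime_s"])
    return manifest


def generate_report(outdir: str | Path) -> dict:
    """Collate stage outputs into report.json + a plain-text summary.

    Missing stage outputs are noted as absent, never fatal.
    """
    outdir = Path(outdir)
    report: dict = {"version": __version__}
    lines = [f"pirnasig v{__version__} report", "=" * 32]

    def absent(name):
        report[name] = None
        lines.append(f"{name}: absent")

    scores = outdir / "signature_scores.tsv"
    if scores.exists():
        frame = pd.read_csv(scores, sep="\t")
        report["signature_scores"] = frame.to_dict(orient="records")
        lines.append("\nSignature scores (per library):")
        for r in frame.itertuples(index=False):
            lines.append(f"  {r.sample:24s} Z10={r.z10:8.2f}  Z0={r.z0:6.2f}")
    else:
        absent("signature_scores")

    bias = outdir / "nucleotide_bias.tsv"
    if bias.exists():
        frame = pd.read_csv(bias, sep="\t")
        report["nucleotide_bias"] = frame.to_dict(orient="records")
        both = frame[frame["scope"] == "both"]
        lines.append("\n1U/10A (both strands):")
        for r in both.itertuples(index=False):
            lines.append(f"  {r.sample:24s} {r.signature}: {r.percent:5.1f}% of {r.n_eligible}")
    else:
        absent("nucleotide_bias")

    inter = outdir / "interaction_summary.json"
    if inter.exists():
        report["interactions"] = json.loads(inter.read_text())
        gi = report["interactions"].get("gi") or {}
        if gi:
            lines.append(
                f"\nGI: {gi.get('n_strong')}/{gi.get('n_tes')} de-silenced TEs with GI > 2 "
                f"({gi.get('percent_strong', float('nan')):.0f}%)"
            )
    else:
        absent("interactions")

    ip = outdir / "ip_overlap.json"
    if ip.exists():
        report["ip_overlap"] = json.loads(ip.read_text())
        lines.append(f"\nIP overlap: {report['ip_overlap'].get('any', 0):.1f}% of reads in a PIWI group")
    else:
        absent("ip_overlap")

    (outdir / "report.json").write_text(json.dumps(report, indent=2, default=str))
    (outdir / "report.txt").write_text("\n".join(lines) + "\n")
    return report
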