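"""End-to-end scenario orchestration on synthetic admixed genomes.

A scenario builds continental reference panels (African, European,
Native American, plus an East African panel that itself carries
European admixture), simulates three-way admixed target genomes with
known ancestry truth, paints them against the unconfounded panels,
masks the non-African genome, runs the four D-test configurations
(Native, European, East African unmasked, East African after African
masking), estimates per-individual ancestry fractions (painting-based
and EM-based), and dates the admixture from tract lengths.  Every stage
draws from a substream of one top-level seed, so a fixed seed reproduces
every number byte for byte.
"""
from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from . import ancestry_paint, dstat, proportions, simulate, tract_dating, vcfio
from .tracts import UNASSIGNED, write_tracts

log = logging.getLogger(__name__)

ALL_STAGES = ("simulate", "paint", "proportions", "dstat", "dating")


@dataclasses.dataclass
class ScenarioConfig:
    """Study conditions for the synthetic three-way admixture scenario.

    Defaults reproduce the published best-fit history: a founding African
    population receiving a European pulse of 11.9 % thirteen generations
    ago and a Native American pulse of 11.6 % ten generations ago, typed
    on strongly differentiated continental panels, with an East African
    panel that is itself 40 % European-admixed (the confounder behind the
    masking-artifact experiment).
    """

    seed: int = 0
    # genome
    n_chrom: int = 22
    chrom_morgans: float = 1.5
    n_sites: int = 150_000
    # panels
    fst: dict = dataclasses.field(
        default_factory=lambda: {"AFR": 0.15, "EUR": 0.15, "NAT": 0.15, "EAF": 0.15})
    panel_n_hap: int = 100
    eaf_european_fraction: float = 0.4
    # admixture history (founding AFR; pulses oldest first)
    founding: str = "AFR"
    pulses: list = dataclasses.field(default_factory=lambda: [
        {"generation": 13, "ancestry": "EUR", "fraction": 0.119},
        {"generation": 10, "ancestry": "NAT", "fraction": 0.116},
    ])
    pop_size: int = 500
    n_admixed: int = 42          # diploid target genomes with truth tracts
    n_paint: int = 6             # targets painted and used in the D tests
    # painting / HMM
    window_size: int = 30
    n_pcs: int = 2
    switch_rate: float = 10.0
    posterior_threshold: float = 0.8
    # D statistics
    block_bp: int = 5_000_000
    z_threshold: float = -2.0
    # dating
    years_per_generation: float = 30.0
    stages: tuple = ALL_STAGES

    def pulse_history(self) -> simulate.PulseHistory:
        return simulate.PulseHistory(
            self.founding,
            tuple(simulate.Pulse(p["generation"], p["ancestry"], p["fraction"])
                  for p in self.pulses))

    def genetic_map(self) -> vcfio.GeneticMap:
        return vcfio.GeneticMap.uniform(self.n_chrom, self.chrom_morgans)

    @classmethod
    def from_yaml(cls, path) -> "ScenarioConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown scenario keys: {sorted(unknown)}")
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["stages"] = list(d["stages"])
        return d


def _round_floats(obj, ndigits: int = 10):
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    if isinstance(obj, (np.floating,)):
        return round(float(obj), ndigits)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    return obj


def run_scenario(config: ScenarioConfig, outdir=None, seed: int | None = None) -> dict:
    """Run the configured scenario and return (and optionally write) a report."""
    if seed is not None:
        config = dataclasses.replace(config, seed=seed)
    stages = set(config.stages)
    unknown = stages - set(ALL_STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    ss = np.random.SeedSequence(config.seed)
    streams = {name: np.random.default_rng(s)
               for name, s in zip(("freqs", "panels", "admix", "paintall", "em"),
                                  ss.spawn(5))}
    gmap = config.genetic_map()
    history = config.pulse_history()
    truth_fracs = history.expected_fractions()
    report: dict = {"config": config.to_dict(),
                    "truth": {"expected_fractions": truth_fracs}}

    log.info("stage simulate: %d sites, %d-haplotype panels", config.n_sites,
             config.panel_n_hap)
    freqs = simulate.sample_ref_freqs(
        config.n_sites, ["AFR", "EUR", "NAT", "EAF"], config.fst,
        rng=streams["freqs"], genetic_map=gmap)
    # the East African panel is itself European-admixed (frequency-level
    # mixture: its haplotypes are exchangeable draws from the mixed frequency)
    alpha = config.eaf_european_fraction
    freqs_conf = freqs.with_population(
        "EAF_ADMIXED", (1.0 - alpha) * freqs.freq("EAF") + alpha * freqs.freq("EUR"))
    panels = {}
    for pop in ("AFR", "EUR", "NAT"):
        panels[pop] = simulate.simulate_panel(freqs, pop, config.panel_n_hap,
                                              rng=streams["panels"])
    panels["EAF"] = simulate.simulate_panel(freqs_conf, "EAF_ADMIXED",
                                            config.panel_n_hap,
                                            rng=streams["panels"],
                                            sample_prefix="EAF_")
    for s in panels["EAF"].samples:
        panels["EAF"].populations[s] = "EAF"

    paths = simulate.simulate_admixed_forward(
        history, gmap, pop_size=config.pop_size, n_out=2 * config.n_admixed,
        rng=streams["admix"])
    targets = simulate.paint_alleles(paths, freqs, rng=streams["admix"],
                                     sample_prefix="TOC_", population="TOC")
    table = vcfio.merge_samples([panels["AFR"], panels["EUR"], panels["NAT"],
                                 panels["EAF"], targets])
    truth_by_hap = {hid: p for hid, p in
                    zip(targets.haplotype_ids(), paths)}
    realized = ancestry_paint.global_fractions(paths)
    report["truth"]["realized_fractions"] = {
        k: v for k, v in realized.items() if k != UNASSIGNED}

    artifacts: dict[str, object] = {"truth_tracts": truth_by_hap}
    paint_samples = targets.samples[:config.n_paint]
    paint_hids = [f"{s}_h{j}" for s in paint_samples for j in (0, 1)]

    calls: dict = {}
    if "paint" in stages:
        log.info("stage paint: %d query haplotypes", len(paint_hids))
        ref_panels = {p: panels[p].samples for p in ("AFR", "EUR", "NAT")}
        refs = vcfio.merge_samples([panels["AFR"], panels["EUR"], panels["NAT"]])
        queries = targets.subset_samples(paint_samples)
        _post, calls = ancestry_paint.paint_haplotypes(
            refs, ref_panels, queries, gmap, config.window_size, config.n_pcs,
            config.switch_rate, config.posterior_threshold)
        artifacts["called_tracts"] = calls
        frac_paint = {}
        for s in paint_samples:
            frac_paint[s] = ancestry_paint.global_fractions(
                [calls[f"{s}_h0"], calls[f"{s}_h1"]])
        report["painting"] = {
            "per_individual_fractions": frac_paint,
            "pooled_fractions": ancestry_paint.global_fractions(
                [calls[h] for h in paint_hids]),
        }

    if "proportions" in stages:
        log.info("stage proportions: supervised EM on %d individuals",
                 len(paint_samples))
        dos = targets.subset_samples(paint_samples).dosage()
        em = {}
        for i, s in enumerate(paint_samples):
            est = proportions.supervised_em(dos[:, i], freqs,
                                            labels=["AFR", "EUR", "NAT"])
            em[s] = est.as_dict()
        report["proportions"] = {"per_individual": em}
        if "paint" in stages:
            agree = {}
            for s in paint_samples:
                fp = report["painting"]["per_individual_fractions"][s]
                agree[s] = max(abs(fp.get(k, 0.0) - em[s][k])
                               for k in ("AFR", "EUR", "NAT"))
            report["proportions"]["max_abs_diff_vs_painting"] = agree

    if "dstat" in stages:
        log.info("stage dstat: four test configurations")
        dd = {}
        dd["native"] = dstat.dstat_test(table, "AFR", paint_samples, "NAT",
                                        block_bp=config.block_bp,
                                        config="D(AFR, TOC; NAT, AA)")
        dd["european"] = dstat.dstat_test(table, "AFR", paint_samples, "EUR",
                                          block_bp=config.block_bp,
                                          config="D(AFR, TOC; EUR, AA)")
        dd["east_african_unmasked"] = dstat.dstat_test(
            table, "AFR", paint_samples, "EAF", block_bp=config.block_bp,
            config="D(AFR, TOC; EAF, AA)")
        if "paint" in stages:
            masked = ancestry_paint.mask_genome(table, calls, "AFR", gmap)
        else:       # no calls available: mask on simulation truth instead
            masked = ancestry_paint.mask_genome(
                table, {h: truth_by_hap[h] for h in paint_hids}, "AFR", gmap)
        dd["east_african_masked"] = dstat.dstat_test(
            masked, "AFR", paint_samples, "EAF", block_bp=config.block_bp,
            config="D(AFR, TOC_masked; EAF, AA)")
        report["dstat"] = {
            name: {"config": r.config, "d": r.d, "se": r.se, "z": r.z,
                   "n_sites": r.n_sites, "n_blocks": r.n_blocks,
                   "significant": bool(r.z < config.z_threshold)}
            for name, r in dd.items()}

    if "dating" in stages:
        log.info("stage dating: tract-length fits")
        dating: dict = {}
        pulse_labels = [p["ancestry"] for p in config.pulses]
        truth_set = tract_dating.extract_tracts(paths)
        if pulse_labels:
            order = (config.founding, *pulse_labels[:2])
            fits, comb = tract_dating.fit_two_pulse_marginal(truth_set, order) \
                if len(order) == 3 else \
                ([tract_dating.fit_single_pulse(truth_set, config.founding)], None)
            if comb is None:
                comb = fits[0].neg_loglik
            dating["truth_fit"] = _fit_report(fits, comb,
                                              config.years_per_generation)
            if "paint" in stages:
                call_set = tract_dating.extract_tracts(
                    [calls[h] for h in paint_hids])
                fits_c, comb_c = tract_dating.fit_two_pulse_marginal(
                    call_set, order) if len(order) == 3 else \
                    ([tract_dating.fit_single_pulse(call_set, config.founding)], None)
                if comb_c is None:
                    comb_c = fits_c[0].neg_loglik
                dating["calls_fit"] = _fit_report(fits_c, comb_c,
                                                  config.years_per_generation)
        else:
            dating["note"] = "no pulses configured; nothing to date"
        report["dating"] = dating

    report = _round_floats(report)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_tracts(truth_by_hap, gmap, outdir / "truth_tracts.tsv")
        if calls:
            write_tracts(calls, gmap, outdir / "called_tracts.tsv")
        with open(outdir / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
        log.info("wrote %s", outdir / "report.json")
    return report


def _fit_report(fits, combined_neg_loglik, years_per_generation) -> dict:
    out = {"combined_neg_loglik": combined_neg_loglik, "pulses": []}
    for f in fits:
        out["pulses"].append({
            "ancestry": f.ancestry, "T": f.T, "T_raw": f.T_raw, "m": f.m,
            "years": tract_dating.generations_to_years(f.T, years_per_generation),
            "neg_loglik": f.neg_loglik, "converged": f.converged,
            "n_tracts": f.n_tracts,
        })
    return out


def null_scenario_config(**overrides) -> ScenarioConfig:
    """A zero-admixture control: pure founding ancestry, same machinery."""
    cfg = ScenarioConfig(**overrides)
    return dataclasses.replace(cfg, pulses=[])
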