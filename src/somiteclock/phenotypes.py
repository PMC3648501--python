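"""In-silico perturbation fixtures: the knockout/overexpression phenotype matrix.

Each fixture pairs a perturbation schedule with machine-checkable expected
outcomes (oscillation kept or lost, level up or down, delayed or immediate
responses, phase classes), mirroring the wet-lab-motivated simulation
experiments the models were built to reproduce: ligand and receptor
knockouts, feedback-loop knockouts (Lfng, Hes7, Axin2, Nkd1), input
removal/scaling and Axin2 overexpression, on each of the three models.

Checks are declarative and evaluated by ``run_fixture`` against a
reference (unperturbed) and a perturbed trajectory started from the same
burned-in state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .models import build_model
from .network import Perturbation, PathwayModel
from .oscillometry import (
    count_periods,
    detect_peaks,
    measure,
    phase_relation,
    response_delay,
)
from .simulate import SimulationConfig, Trajectory, burn_in, integrate

__all__ = [
    "Check",
    "CheckResult",
    "PhenotypeFixture",
    "FixtureResult",
    "phenotype_suite",
    "run_fixture",
    "run_phenotype_suite",
]

NOTCH_GENES = ("Lfng_mRNA_cyt", "Hes7_mRNA_cyt")
WNT_GENES_ISOLATED = ("Axin2_mRNA_cyt", "Lef1_mRNA_cyt", "Dll1_mRNA_cyt")
WNT_GENES_COMBINED = ("Axin2_mRNA_cyt", "Dll1_mRNA_cyt")
ALL_COMBINED = ("Lfng_mRNA_cyt", "Hes7_mRNA_cyt", "Nkd1_mRNA_cyt",
                "Axin2_mRNA_cyt", "Dll1_mRNA_cyt")


@dataclass
class Check:
    """One machine-checkable expectation on the perturbed trajectory.

    kind:
      oscillating        species oscillates (expect=True) or not, over the
                         trailing ``window`` minutes
      period_in          period within [lo, hi] minutes
      phase              phase class of (species, species_b)
      level_ratio        pert/ref statistic ratio over [t0, end] in [lo, hi]
                         (stat: mean or max)
      final_below        final value below ``hi`` x reference pre-event peak
      count_below        complete cycles on the full horizon < ``hi``
      period_ratio       pert period / ref period within [lo, hi]
      delay_in           response_delay (direction via ``stat``) in [lo, hi]
      peaks_at_least     >= ``lo`` peaks in [t0, t1]
      dip_then_recover   max over [event, t0] below ``hi`` x ref, then max
                         over [t0, t1] above ``lo`` x the dip max
    """

    kind: str
    species: str
    expect: bool = True
    species_b: str | None = None
    lo: float | None = None
    hi: float | None = None
    t0: float | None = None
    t1: float | None = None
    window: float = 480.0
    stat: str = "mean"
    phase_class: str | None = None


@dataclass
class CheckResult:
    check: Check
    passed: bool
    observed: object


@dataclass
class PhenotypeFixture:
    name: str
    model_id: str
    schedule: list[Perturbation]
    description: str
    checks: list[Check]
    t_end: float = 1200.0


@dataclass
class FixtureResult:
    fixture: PhenotypeFixture
    passed: bool
    checks: list[CheckResult] = field(default_factory=list)


def _slice_from(traj: Trajectory, t0: float, species: str) -> np.ndarray:
    mask = traj.times >= t0
    return traj[species][mask]


def _eval_check(c: Check, pert: Trajectory, ref: Trajectory,
                event_time: float) -> CheckResult:
    if c.kind == "oscillating":
        s = measure(pert, c.species, window=c.window)
        return CheckResult(c, s.is_oscillating == c.expect, s.is_oscillating)
    if c.kind == "period_in":
        s = measure(pert, c.species, window=c.window)
        ok = s.is_oscillating and c.lo <= s.period <= c.hi
        return CheckResult(c, ok, s.period if s.is_oscillating else None)
    if c.kind == "phase":
        pr = phase_relation(pert, c.species, c.species_b)
        return CheckResult(c, pr.classification.value == c.phase_class,
                           (pr.classification.value, round(pr.lag, 1)))
    if c.kind == "level_ratio":
        t0 = c.t0 if c.t0 is not None else event_time
        a = _slice_from(pert, t0, c.species)
        b = _slice_from(ref, t0, c.species)
        va = float(a.mean() if c.stat == "mean" else a.max())
        vb = float(b.mean() if c.stat == "mean" else b.max())
        r = va / vb if vb > 0 else np.inf
        lo = -np.inf if c.lo is None else c.lo
        hi = np.inf if c.hi is None else c.hi
        return CheckResult(c, lo <= r <= hi, round(r, 3))
    if c.kind == "final_below":
        pre_peak = float(ref[c.species][ref.times <= event_time].max())
        final = float(pert[c.species][-1])
        r = final / pre_peak if pre_peak > 0 else 0.0
        return CheckResult(c, r < c.hi, round(r, 4))
    if c.kind == "count_below":
        n = count_periods(pert, c.species)
        return CheckResult(c, n < c.hi, n)
    if c.kind == "period_ratio":
        sp = measure(pert, c.species, window=c.window)
        sr = measure(ref, c.species, window=c.window)
        if not (sp.is_oscillating and sr.is_oscillating):
            return CheckResult(c, False, None)
        r = sp.period / sr.period
        return CheckResult(c, c.lo <= r <= c.hi, round(r, 3))
    if c.kind == "delay_in":
        d = response_delay(pert, ref, c.species, event_time)
        ok = (not np.isnan(d)) and c.lo <= d <= c.hi
        return CheckResult(c, ok, None if np.isnan(d) else round(d, 1))
    if c.kind == "peaks_at_least":
        w = pert.window(c.t0, c.t1)
        n = len(detect_peaks(w, c.species))
        return CheckResult(c, n >= c.lo, n)
    if c.kind == "dip_then_recover":
        ref_max = float(ref[c.species][(ref.times >= event_time)
                                       & (ref.times <= c.t0)].max())
        dip = float(pert[c.species][(pert.times >= event_time)
                                    & (pert.times <= c.t0)].max())
        later = float(pert[c.species][(pert.times >= c.t0)
                                      & (pert.times <= c.t1)].max())
        dipped = dip < c.hi * ref_max
        recovered = later > c.lo * dip
        return CheckResult(c, dipped and recovered,
                           (round(dip / ref_max, 3), round(later / dip, 3)))
    raise ValueError(f"unknown check kind {c.kind!r}")


def run_fixture(
    fixture: PhenotypeFixture,
    model: PathwayModel | None = None,
    config: SimulationConfig | None = None,
    reference: Trajectory | None = None,
) -> FixtureResult:
    """Evaluate one fixture; builds/burns in the reference model if needed."""
    if model is None:
        model = build_model(fixture.model_id)
        res = burn_in(model, config or SimulationConfig())
        model.set_initial_state(res.state)
    cfg = config or SimulationConfig()
    cfg = SimulationConfig(t_end=fixture.t_end, output_dt=cfg.output_dt,
                           rel_tol=cfg.rel_tol, abs_tol=cfg.abs_tol,
                           max_burn_in=cfg.max_burn_in)
    if reference is None:
        reference = integrate(model, cfg)
    pert = integrate(model, cfg, fixture.schedule)
    event_time = fixture.schedule[0].time if fixture.schedule else 0.0
    results = [_eval_check(c, pert, reference, event_time)
               for c in fixture.checks]
    return FixtureResult(fixture, all(r.passed for r in results), results)


def run_phenotype_suite(
    model_id: str,
    model: PathwayModel | None = None,
    config: SimulationConfig | None = None,
) -> list[FixtureResult]:
    """Run every fixture for one model against a shared burned-in reference."""
    if model is None:
        model = build_model(model_id)
        res = burn_in(model, config or SimulationConfig())
        model.set_initial_state(res.state)
    cfg = config or SimulationConfig()
    ref_cache: dict[float, Trajectory] = {}
    out = []
    for fx in phenotype_suite(model_id):
        if fx.t_end not in ref_cache:
            run_cfg = SimulationConfig(t_end=fx.t_end, output_dt=cfg.output_dt,
                                       rel_tol=cfg.rel_tol, abs_tol=cfg.abs_tol,
                                       max_burn_in=cfg.max_burn_in)
            ref_cache[fx.t_end] = integrate(model, run_cfg)
        out.append(run_fixture(fx, model, cfg, ref_cache[fx.t_end]))
    return out


# ---------------------------------------------------------------------------
# the fixture matrix
# ---------------------------------------------------------------------------


def _ko(gene, t):
    return Perturbation("knockout_gene", gene, t)


def phenotype_suite(model_id: str) -> list[PhenotypeFixture]:
    """The full perturbation-phenotype matrix for one model."""
    if model_id == "notch":
        return _notch_suite()
    if model_id == "wnt":
        return _wnt_suite()
    if model_id == "combined":
        return _combined_suite()
    raise KeyError(f"unknown model {model_id!r}")


def _notch_suite() -> list[PhenotypeFixture]:
    F, C = PhenotypeFixture, Check
    osc_dead = [C("oscillating", g, expect=False) for g in NOTCH_GENES]
    collapse = [C("final_below", g, hi=0.01) for g in NOTCH_GENES]
    return [
        F("notch_baseline", "notch", [],
          "constant Dll1 signal: both target genes cycle at ~120 min, "
          "in phase with NICD and in antiphase with nuclear Hes7",
          [C("period_in", g, lo=108, hi=132, window=1200) for g in NOTCH_GENES]
          + [C("phase", "Lfng_mRNA_cyt", species_b="Hes7_mRNA_cyt",
               phase_class="in_phase"),
             C("phase", "Lfng_mRNA_cyt", species_b="NICD_nuc",
               phase_class="in_phase"),
             C("phase", "Lfng_mRNA_cyt", species_b="Hes7_protein_nuc",
               phase_class="antiphase")]),
        F("notch_dll1_ko", "notch", [_ko("Dll1", 120)],
          "ligand knockout: oscillation lost, target levels collapse",
          osc_dead + collapse),
        F("notch_receptor_ko", "notch",
          [Perturbation("knockout_species", "Notch_receptor", 120)],
          "receptor knockout: same catastrophic loss as the ligand knockout",
          osc_dead + collapse),
        F("notch_lfng_ko", "notch", [_ko("Lfng", 120)],
          "big-loop knockout: Hes7 keeps cycling, its maximum rises a little",
          [C("oscillating", "Hes7_mRNA_cyt", window=600),
           C("level_ratio", "Hes7_mRNA_cyt", stat="max", t0=600,
             lo=1.005, hi=1.6)]),
        F("notch_hes7_ko", "notch", [_ko("Hes7", 120)],
          "small-loop knockout: Lfng strongly up, oscillation destroyed; "
          "NICD decays to near zero with a delay of about one period",
          [C("level_ratio", "Lfng_mRNA_cyt", stat="max", t0=120, t1=480,
             lo=1.5, hi=None),
           C("oscillating", "Lfng_mRNA_cyt", expect=False),
           C("final_below", "NICD_nuc", hi=0.05),
           C("level_ratio", "NICD_nuc", stat="max", t0=120, t1=240,
             lo=0.5, hi=None)]),
    ]


def _wnt_suite() -> list[PhenotypeFixture]:
    F, C = PhenotypeFixture, Check
    return [
        F("wnt_baseline", "wnt", [],
          "constant Wnt: all three target genes cycle at ~120 min in phase; "
          "active Dsh antiphase to the degradation complex and Axin2, the "
          "complex antiphase to the beta-catenin/Lef1 activator",
          [C("period_in", g, lo=108, hi=132, window=1200)
           for g in WNT_GENES_ISOLATED]
          + [C("phase", "Axin2_mRNA_cyt", species_b="Dll1_mRNA_cyt",
               phase_class="in_phase"),
             C("phase", "Axin2_mRNA_cyt", species_b="Lef1_mRNA_cyt",
               phase_class="in_phase"),
             C("phase", "Dsh_active", species_b="GSK3_Axin2",
               phase_class="antiphase"),
             C("phase", "Dsh_active", species_b="Axin2_protein",
               phase_class="antiphase"),
             C("phase", "GSK3_Axin2", species_b="bcat_Lef1",
               phase_class="antiphase")]),
        F("wnt_input_removed", "wnt",
          [Perturbation("remove_input", "Wnt", 120)],
          "removing the extracellular signal: active Dsh collapses at once, "
          "target expression descends and stops cycling (judged on the last "
          "360 min, past the damped ringing of the approach to rest)",
          [C("oscillating", g, expect=False, window=360.0)
           for g in WNT_GENES_ISOLATED]
          + [C("final_below", "Dsh_active", hi=0.01),
             C("final_below", "Axin2_mRNA_cyt", hi=0.2)]),
        F("wnt_input_doubled", "wnt",
          [Perturbation("scale_input", "Wnt", 0, factor=2.0)],
          "doubling the signal: neither period nor amplitude move "
          "appreciably (the receptor-level response is saturated)",
          [C("period_ratio", g, lo=0.95, hi=1.05, window=600)
           for g in WNT_GENES_ISOLATED]
          + [C("level_ratio", g, stat="max", t0=600, lo=0.90, hi=1.10)
             for g in WNT_GENES_ISOLATED]),
        F("wnt_axin2_ko", "wnt", [_ko("Axin2", 120)],
          "feedback knockout: Dll1 is upregulated and stops cycling",
          [C("level_ratio", "Dll1_mRNA_cyt", stat="mean", t0=700,
             lo=1.3, hi=None),
           C("oscillating", "Dll1_mRNA_cyt", expect=False)]),
    ]


def _combined_suite() -> list[PhenotypeFixture]:
    F, C = PhenotypeFixture, Check

    def osc(genes, expect=True, window=480.0):
        return [C("oscillating", g, expect=expect, window=window)
                for g in genes]

    return [
        F("combined_baseline_oscillation", "combined", [],
          "constant Wnt: all five target genes cycle at ~120 min",
          [C("period_in", g, lo=108, hi=132, window=1200)
           for g in ALL_COMBINED]),
        F("combined_phase_structure", "combined", [],
          "Lfng, Hes7 and Nkd1 cycle together; Axin2 and Dll1 in antiphase",
          [C("phase", "Lfng_mRNA_cyt", species_b="Hes7_mRNA_cyt",
             phase_class="in_phase"),
           C("phase", "Lfng_mRNA_cyt", species_b="Nkd1_mRNA_cyt",
             phase_class="in_phase"),
           C("phase", "Lfng_mRNA_cyt", species_b="Axin2_mRNA_cyt",
             phase_class="antiphase"),
           C("phase", "Lfng_mRNA_cyt", species_b="Dll1_mRNA_cyt",
             phase_class="antiphase")]),
        F("combined_notch_ko_notch_targets", "combined",
          [Perturbation("knockout_species", "Notch_receptor", 120)],
          "receptor knockout: Notch targets stop cycling and collapse",
          osc(NOTCH_GENES, expect=False, window=360.0)
          + [C("final_below", g, hi=0.05) for g in NOTCH_GENES]),
        F("combined_notch_ko_wnt_targets", "combined",
          [Perturbation("knockout_species", "Notch_receptor", 120)],
          "receptor knockout: Wnt targets settle lower and stop cycling "
          "(judged past the damped ringing, on the last 360 min)",
          osc(WNT_GENES_COMBINED, expect=False, window=360.0)
          + [C("level_ratio", "Axin2_mRNA_cyt", stat="mean", t0=700,
               lo=None, hi=0.8)]),
        F("combined_lfng_ko_hes7", "combined", [_ko("Lfng", 120)],
          "Lfng knockout: Hes7 keeps cycling with a higher maximum",
          [C("oscillating", "Hes7_mRNA_cyt", window=600),
           C("level_ratio", "Hes7_mRNA_cyt", stat="max", t0=600,
             lo=1.005, hi=None)]),
        F("combined_lfng_ko_wnt_targets", "combined", [_ko("Lfng", 120)],
          "Lfng knockout: freed NICD sequesters active Dsh; Wnt targets are "
          "downregulated after a ~30 min delay and stop cycling",
          osc(WNT_GENES_COMBINED, expect=False, window=360.0)
          + [C("level_ratio", "Axin2_mRNA_cyt", stat="mean", t0=400,
               lo=None, hi=0.75),
             C("delay_in", "Axin2_mRNA_cyt", lo=15, hi=45)]),
        F("combined_hes7_ko_lfng", "combined", [_ko("Hes7", 240)],
          "Hes7 knockout: Lfng strongly upregulated, oscillation destroyed",
          [C("level_ratio", "Lfng_mRNA_cyt", stat="max", t0=240, t1=720,
             lo=1.5, hi=None),
           C("oscillating", "Lfng_mRNA_cyt", expect=False, window=360)]),
        F("combined_hes7_ko_wnt_targets", "combined", [_ko("Hes7", 240)],
          "Hes7 knockout: the Wnt side keeps cycling (the NICD-Dsh pool "
          "buffers the extra Nkd1)",
          osc(WNT_GENES_COMBINED, window=600)),
        F("combined_wnt_half", "combined",
          [Perturbation("scale_input", "Wnt", 0, factor=0.5)],
          "halving Wnt lengthens the period: fewer than ten full cycles "
          "fit in 1200 minutes",
          [C("count_below", g, hi=10) for g in ALL_COMBINED]
          + osc(ALL_COMBINED, window=1200)),
        F("combined_wnt_x10", "combined",
          [Perturbation("scale_input", "Wnt", 0, factor=10.0)],
          "a tenfold Wnt increase leaves the period essentially unchanged",
          [C("period_ratio", g, lo=0.90, hi=1.10, window=600)
           for g in ALL_COMBINED]),
        F("combined_wnt_removed_200", "combined",
          [Perturbation("remove_input", "Wnt", 200)],
          "removing Wnt at 200 min: every target gene is downregulated and "
          "stops cycling (Dll1 starves the Notch side)",
          osc(ALL_COMBINED, expect=False, window=360.0)
          + [C("level_ratio", g, stat="mean", t0=900, lo=None, hi=0.5)
             for g in ALL_COMBINED]),
        F("combined_axin2_ko", "combined", [_ko("Axin2", 120)],
          "Axin2 knockout: Dll1 up and non-cycling; Notch targets keep "
          "oscillating",
          [C("level_ratio", "Dll1_mRNA_cyt", stat="mean", t0=700,
             lo=1.3, hi=None),
           C("oscillating", "Dll1_mRNA_cyt", expect=False)]
          + osc(NOTCH_GENES, window=600)),
        F("combined_axin2_overexpressed", "combined",
          [Perturbation("overexpress_gene", "Axin2", 120, factor=3.0)],
          "Axin2 overexpression: Dll1 down; Notch targets (especially Lfng) "
          "up but still cycling",
          [C("level_ratio", "Dll1_mRNA_cyt", stat="mean", t0=600,
             lo=None, hi=0.8),
           C("level_ratio", "Lfng_mRNA_cyt", stat="max", t0=600,
             lo=1.05, hi=None)]
          + osc(NOTCH_GENES, window=600)),
        F("combined_wnt_removed_240_nkd1", "combined",
          [Perturbation("remove_input", "Wnt", 240)],
          "removing Wnt at 240 min: Nkd1 expression drops but still shows "
          "cycles in the following window",
          [C("peaks_at_least", "Nkd1_mRNA_cyt", lo=3, t0=240, t1=900),
           C("level_ratio", "Nkd1_mRNA_cyt", stat="max", t0=300, t1=900,
             lo=None, hi=1.0)]),
        F("combined_dll1_ko_240_nkd1", "combined", [_ko("Dll1", 240)],
          "Dll1 knockout raises Nkd1 (so Wnt's effect on Nkd1 is not routed "
          "through the Notch pathway)",
          [C("level_ratio", "Nkd1_mRNA_cyt", stat="mean", t0=600,
             lo=1.2, hi=None)]),
        F("combined_hes7_ko_nkd1", "combined", [_ko("Hes7", 120)],
          "Hes7 knockout: Nkd1 upregulated and non-cycling",
          [C("level_ratio", "Nkd1_mRNA_cyt", stat="mean", t0=600,
             lo=1.3, hi=None),
           C("oscillating", "Nkd1_mRNA_cyt", expect=False)]),
        F("combined_nkd1_ko_wnt_amplitude", "combined", [_ko("Nkd1", 120)],
          "Nkd1 knockout frees active Dsh: Wnt-target amplitudes rise "
          "after a delay of about an hour",
          [C("level_ratio", "Axin2_mRNA_cyt", stat="max", t0=480,
             lo=1.2, hi=None),
           C("delay_in", "Axin2_mRNA_cyt", lo=30, hi=90)]),
        F("combined_nkd1_ko_notch_response", "combined", [_ko("Nkd1", 120)],
          "Nkd1 knockout: Notch targets dip at once (Dsh soaks up NICD) "
          "and recover about one period later via rising Dll1",
          [C("dip_then_recover", "Lfng_mRNA_cyt", t0=300, t1=800,
             hi=0.92, lo=1.05)]),
    ]
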