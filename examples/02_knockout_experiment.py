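"""In-silico gene knockout: what Hes7 loss does to the clock.

Knocks out the Hes7 gene (the core pacemaker repressor) at t = 120 min in
the isolated Notch model and compares the outcome with the unperturbed
run.  Expected output: Lfng transcription surges several-fold once its
repressor is gone, then the oscillation collapses because the
delayed-negative-feedback pacemaker has been removed; NICD drains away as
the accumulated Lfng blocks receptor cleavage.
"""

from somiteclock import (
    Perturbation,
    SimulationConfig,
    build_notch_model,
    integrate,
    measure,
)

model = build_notch_model()
cfg = SimulationConfig(t_end=1200.0)

reference = integrate(model, cfg)
knockout = integrate(model, cfg, [Perturbation("knockout_gene", "Hes7", 120.0)])

ref_peak = reference["Lfng_mRNA_cyt"].max()
ko_transient = knockout["Lfng_mRNA_cyt"][(knockout.times >= 120)
                                         & (knockout.times <= 480)].max()
late = measure(knockout, "Lfng_mRNA_cyt", window=480.0)
nicd_final = knockout["NICD_nuc"][-1]

print(f"Lfng mRNA reference peak:        {ref_peak:8.2f} a.u.")
print(f"Lfng mRNA surge after knockout:  {ko_transient:8.2f} a.u. "
      f"({ko_transient / ref_peak:.1f}x the reference peak)")
print(f"still oscillating afterwards:    {late.is_oscillating}")
print(f"nuclear NICD at 1200 min:        {nicd_final:8.4f} a.u. "
      f"(reference peak {reference['NICD_nuc'].max():.2f})")
print("\nthe small (Hes7) feedback loop is the pacemaker: removing it "
      "destroys the rhythm even though the big (Lfng) loop is intact")
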