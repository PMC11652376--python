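"""End-to-end motif discovery on a synthetic transcriptome.

Runs the full desk-scale study once: generate a corpus with four planted
motif classes, pretrain a tiny encoder, fine-tune paired true/background
TE classifiers, extract the attention-contrast scores, and report the
discovered secondary-structure motifs and rG4s together with the
AUG-anchored meta-profile. Takes a few minutes on one CPU.
"""

import numpy as np

from ribolens import assess_recovery, run_recovery_study

result = run_recovery_study(seed=1)

print(f"true model     macro F1 = {result.true_report.f1:.3f}")
print(f"background     macro F1 = {result.background_report.f1:.3f}")

offsets, profile, n = result.metaprofile
peak = offsets[np.nanargmax(profile)]
print(f"meta-profile peak at offset {peak} from the AUG")

print(f"\n{len(result.motif_reports)} secondary-structure motif clusters:")
for rep in result.motif_reports:
    print(f"  {rep.consensus:<16} dir={rep.direction:<8} n={rep.member_count}"
          f" OR={rep.odds_ratio:.2f} p={rep.p_raw:.2e} APIC={rep.apic:.2f}")

print(f"\n{len(result.rg4_hits)} rG4s pass q < 0.01; first few:")
for h in result.rg4_hits[:3]:
    print(f"  {h.transcript_id} [{h.start},{h.end}) {h.sequence} q={h.q_bh:.3g}")

recovery = assess_recovery(result)
print("\nrecovery against the plant ledger:",
      {k: recovery[k] for k in ("kozak", "gc_stem", "mixed_stem", "rg4")})
# A successful run reports the GC-stem hairpin as low-TE, the mixed-stem
# hairpin as high-TE, planted rG4s at q < 0.01, and a contrast peak just
# upstream of the AUG where the Kozak-like context was planted.
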