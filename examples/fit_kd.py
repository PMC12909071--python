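"""Fit a dissociation constant from a fluorescence-polarization titration.

With 10 nM labelled RNA, protein binding depletes the free ligand, so the
exact quadratic one-site model is fitted per replicate (2-fold ladder,
8000 -> 0.488 nM) and K_D reported as mean +/- SD across replicates.
"""

from quadrufold.fp_binding import fit_kd
from quadrufold.synth import gen_fp_curves

series, truth = gen_fp_curves(kd_nm=100.0, noise_sd_mp=2.0, replicates=3, seed=0)
report = fit_kd(series)

print(f"true K_D: {truth['kd_nm']:.0f} nM (noise 2 mP, 3 replicates)")
print(f"fitted  : {report.kd_mean_nm:.1f} +/- {report.kd_sd_nm:.1f} nM")
for i, r in enumerate(report.replicates, 1):
    print(f"  replicate {i}: K_D = {r.model.kd_nm:.1f} nM "
          f"(rmsd {r.rmsd_mp:.2f} mP)")
# the mean lands within ~10% of the generating value at this noise level
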