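"""The ceiling on genomic prediction of a binary trait.

For a disease with prevalence K, a genetic risk score explaining a fraction
rho2 of the liability variance cannot exceed a closed-form AUC, no matter the
model.  At the prevalence of cruciate-ligament rupture in Labrador Retrievers
(K = 0.0579) a perfect score for a trait with liability heritability 0.4 tops
out at 0.86; a score capturing only a quarter of the genetic variance tops
out at 0.69 — context for judging any SNP-based predictor of this trait.
"""

from gprisk import max_liability_auc

K = 0.0579
print(f"prevalence K = {K}")
for rho2 in (0.4, 0.3, 0.2, 0.1, 0.05):
    print(f"  liability variance explained {rho2:4.2f} -> "
          f"max AUC {max_liability_auc(K=K, rho2=rho2):.3f}")
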