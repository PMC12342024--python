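"""Tissue partitioning of one compound under the five distribution models.

Each method predicts tissue:plasma partition coefficients (Kp) from
lipophilicity, ionization and plasma binding; the implied steady-state
volume Vdss = Vp + sum(Vt * Kp) shows how strongly the distribution
assumption alone moves the prediction.
"""

from struct2pk import KP_METHODS, ParameterSet, compute_kp, vdss_from_kp

# a moderately lipophilic, strong base - the regime where methods disagree most
params = ParameterSet(fu=0.1, logp=3.5, mw=400.0, pka_base=9.5)

print(f"compound: logP {params.logp}, fu {params.fu}, basic pKa {params.pka_base}\n")
print(f"{'method':<16} {'muscle':>8} {'adipose':>8} {'liver':>8} {'Vdss mL/kg':>12}")
for method in KP_METHODS:
    kp = compute_kp(method, params)
    vd = vdss_from_kp(kp)
    print(f"{method:<16} {kp['muscle']:>8.2f} {kp['adipose']:>8.2f} "
          f"{kp['liver']:>8.2f} {vd:>12.0f}")
print("\nThe spread in implied Vdss across methods is the distribution-model")
print("uncertainty a single-method prediction would hide.")
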