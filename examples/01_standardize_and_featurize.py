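"""Clean raw SMILES and turn them into model-ready representations.

Salts are stripped to the parent structure, the SMILES is canonicalized,
and the molecule becomes either a 1024-bit Morgan fingerprint or a named
descriptor vector. Tanimoto similarity compares fingerprints.
"""

from struct2pk import (
    compute_logp,
    compute_mw,
    count_halogens,
    featurize,
    standardize_smiles,
    tanimoto_similarity,
)

raw_forms = {
    "diclofenac sodium": "OC(=O)Cc1ccccc1Nc1c(Cl)cccc1Cl.[Na]",
    "propranolol HCl": "CC(C)NCC(O)COc1cccc2ccccc12.Cl",
}

for name, raw in raw_forms.items():
    std = standardize_smiles(raw)
    print(f"{name}:")
    print(f"  standardized: {std}")
    print(f"  MW {compute_mw(std):.1f} g/mol, logP {compute_logp(std):.2f}, "
          f"halogens {count_halogens(std)}")

fp_a = featurize(standardize_smiles(raw_forms["diclofenac sodium"]), "fingerprint")
fp_b = featurize(standardize_smiles(raw_forms["propranolol HCl"]), "fingerprint")
print(f"Tanimoto(diclofenac, propranolol) = {tanimoto_similarity(fp_a, fp_b):.3f}")
print("Low similarity means the two structures share few circular substructures.")
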