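"""Validate tRNA cloverleaf structures and flag a short DHU arm.

A typical cloverleaf has an acceptor stem plus DHU, anticodon and TPsiC
arms.  Some mitochondrial serine tRNAs keep only one complementary pair in
the DHU stem; the report flags that as atypical and says why.
"""

import mitocomp as mc

for name, dhu_pairs in (("canonical tRNA", 4), ("short-DHU tRNA", 1)):
    seq, db = mc.simulate_trna(arm_pairs=(7, dhu_pairs, 5, 5),
                               anticodon="TCT", seed=1)
    cl = mc.partition_cloverleaf(mc.parse_dot_bracket(seq, db))
    rep = mc.arm_report(cl)
    verdict = "typical" if rep["typical"] else \
        "ATYPICAL (" + "; ".join(rep["reasons"]) + ")"
    print(f"{name} ({len(seq)} nt): acceptor {rep['acceptor_pairs']} bp, "
          f"DHU {rep['dhu_pairs']} bp, anticodon arm "
          f"{rep['anticodon_pairs']} bp, TPsiC {rep['tpsic_pairs']} bp, "
          f"anticodon {rep['anticodon']} -> {verdict}")
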