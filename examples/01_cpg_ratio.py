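"""Compute CpG observed/expected ratios for promoter sequences.

The CpG O/E ratio compares the observed count of CG dinucleotides with the
count expected from base composition: O/E = (CpG * N) / (C * G).  Values
near 1 mean CG occurs as often as composition predicts; values well below
1 are the signature of germline DNA methylation eroding CpG sites.
"""

from finlife import count_cpg, oe_ratio

examples = {
    "CpG island-like": "CG" * 30,
    "CpG-rich promoter": "ATCGGATAAACGTTTCGGCTATAACGGC" * 3,
    "CpG-eroded": "ATTGGATAAATGTTTTGGCTATAATGGC" * 3,
    "with ambiguity codes": "ACGTNNNRACGT",
}

for label, seq in examples.items():
    c = count_cpg(seq)
    print(
        f"{label:22s} CpG={c.cpg:3d} C={c.c:3d} G={c.g:3d} N_eff={c.n:3d} "
        f"O/E={c.oe_ratio:.3f}"
    )

# strand invariance: CG is its own reverse complement
seq = "ATCGGATAAACGTTTCGG"
rc = seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]
print(f"\nforward O/E {oe_ratio(seq):.3f} == reverse-complement O/E {oe_ratio(rc):.3f}")
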