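"""Encode transcripts as 100-dimensional feature vectors.

Simulates a handful of lncRNA-like and mRNA-like transcripts, extracts
the full feature matrix and prints the features that most visibly
separate the two classes: mRNA-like sequences carry one long open
reading frame (high ORF coverage), lncRNA-like sequences do not.
"""

from plantlnc import extract_matrix, simulate_sequences

pos, neg = simulate_sequences(5, 5, seed=1, length_range=(200, 500))

for name, sset in (("lncRNA-like", pos), ("mRNA-like", neg)):
    df, _ = extract_matrix(sset, fold_backend="builtin")
    print(f"{name}: {df.shape[0]} sequences x {df.shape[1] - 1} features")
    cols = ["id", "seq_length", "orf_count", "orf_coverage", "orf_length",
            "gc_content", "mfe_norm"]
    print(df[cols].round(2).to_string(index=False))
    print()

# orf_coverage is the percentage of nucleotides inside any detected ORF;
# mRNA-like rows sit near 60-100%, lncRNA-like rows well below 40%.
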