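"""Compare encoding schemes and learning algorithms on one dataset.

All cells share the same train/test split, so differences are attributable
only to the varied factor.  Schemes that see the positional G-run (psnp,
onehot, eiip, chemprop) separate the classes well; the position-free
dinucleotide composition (conposi) lags far behind.
"""

import m5csub as m

corpus = m.simulate_corpus(m.SimConfig(n_transcripts=30, n_pos=250, seed=5))
pos, neg = m.make_labeled_windows(corpus)
ds = m.split_train_test(
    m.RegulatorDataset("NSUN2", "mature_mrna", pos, neg), seed=5
)

print("independent-test AUROC per scheme:")
table = m.compare_features(
    [ds], schemes=("psnp", "onehot", "eiip", "conposi", "chemprop"),
    combinations=("eiip+conposi",), seed=5,
)
print(table.round(3).to_string())

print("\nindependent-test metrics per algorithm (psnp features):")
print(m.compare_algorithms(ds, seed=5).round(3).to_string(index=False))
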