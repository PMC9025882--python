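"""Simulate a corpus and run the full labeling pipeline.

Prints the number of sites surviving each stage: peak overlap, the IVT
false-positive filter, the exon (mature-mRNA) filter, 1:1 negative
sampling, redundancy removal and the 80/20 split.
"""

import m5csub as m

corpus = m.simulate_corpus(
    m.SimConfig(n_transcripts=20, n_pos=150, n_unbound=40, n_ivt=10, seed=3)
)
ds = m.build_dataset(
    corpus.m5c_sites,
    corpus.peaks,
    corpus.transcripts,
    regulator="NSUN2",
    model_kind="mature_mrna",
    ivt_blacklist=corpus.ivt_sites,
    seed=3,
)
for stage, count in ds.stage_counts.items():
    print(f"{stage:22s} {count}")
print(f"train windows          {len(ds.train_idx)}")
print(f"test windows           {len(ds.test_idx)}")
print("every window is 41 nt, C-centered, and in exactly one split")
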