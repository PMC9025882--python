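"""Encode a C-centered RNA window with several feature schemes.

Each encoder maps the same 21-nt window to a numeric vector; the printed
dimensions follow the scheme contracts (composition 16, one-hot 4L,
EIIP L, chemical property 3L, propensity L-1 after fitting).
"""

import m5csub as m

window = "GCGGAUCGAUCGGGCAUGCAU"  # 21 nt, C at the center (index 10)
print(f"window: {window} (center base {window[10]})")

print(f"conposi  dim {m.encode_conposi(window).size:4d}  "
      f"(dinucleotide frequencies, sum={m.encode_conposi(window).sum():.1f})")
print(f"onehot   dim {m.encode_onehot(window).size:4d}")
print(f"eiip     dim {m.encode_eiip(window).size:4d}  "
      f"first 4 values {m.encode_eiip(window)[:4].tolist()}")
print(f"chemprop dim {m.encode_chemprop(window).size:4d}")

# the propensity encoder is a class-contrast statistic: it needs training data
pos = ["GCGGAUCGAUCGGGCAUGCAU", "AUGGAUCGAUCGGGCAUGGGC"]
neg = ["AUAUAUCGAUCUAUCAUGCAU", "GCAUAUCGAUCAAUCAUGCAA"]
model = m.fit_psnp(pos, neg)
vec = m.encode_psnp(window, model)
print(f"psnp     dim {vec.size:4d}  (entries in [-1, 1]; positive entries mark "
      "dinucleotides more typical of substrates)")
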