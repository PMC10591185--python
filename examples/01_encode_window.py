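"""Encode a single 41-bp window into the five feature groups.

Builds one adenine-centred window, encodes it, and prints a few named
features from each group.  The 344 values are what the classifiers see.
"""

from methsemble import encode

window = "GCGT" * 5 + "A" + "GAGG" + "TTCA" * 4  # 41 bp, A at position 21
fv = encode.encode_all(window)
series = fv.to_series()

print(f"window: {window}")
print(f"features: {len(fv.names)} total, census {fv.census()}")
for name in ["DNF:GC", "DNF:AG", "NCP:pos21:ring", "AMIP:k01", "GC:log",
             "MBED:pos21:A", "MBED:pos22:G"]:
    print(f"  {name:16s} = {series[name]:.4f}")

# DNF values are pair counts / 40 and sum to 1; NCP/MBED are the binary
# chemical-property and one-hot codes at each position; AMIP:kXX is the
# mutual information (bits) between bases XX positions apart; GC:log is
# log(1 + GC fraction).
print(f"DNF sum (should be 1): {series.filter(like='DNF:').sum():.6f}")
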