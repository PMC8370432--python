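"""Generate a roving auditory oddball tone sequence.

Tone frequency steps by 50 Hz (range 400-800 Hz) after 3-10 repetitions;
the first tone of each train is the deviant, the sixth the standard.
"""

from dcmerf import generate_roving_sequence

seq = generate_roving_sequence(2000, seed=0)
print(seq.head(12).to_string(index=False))

counts = seq["label"].value_counts()
lengths = seq.groupby("train").size()
print(f"\n{len(seq)} tones in {seq['train'].nunique()} trains "
      f"(lengths {lengths.min()}-{lengths.max()})")
print(f"deviants: {counts.get('deviant', 0)}, "
      f"standards: {counts.get('standard', 0)} — standards are rarer "
      "because only trains of six or more tones contain one.")
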