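"""Extract the 47-feature vector of one segment and see where seizures show.

A level-4 db4 wavelet pyramid splits the 173.61 Hz signal into five
sub-bands (cA4 ~0-5 Hz up to cD1 ~43-87 Hz); nine statistics per band plus
the two Hurst features give the 47-dimensional representation. Because each
segment is min-max scaled to [0, 1] before feature extraction, the features
measure the *shape* of the coefficient distributions, not absolute gain.
"""

from hurstwave import SyntheticSpec, gen_segment
from hurstwave.features import extract_features
from hurstwave.preprocess import preprocess_segment

spec = SyntheticSpec(seed=11)
feats = {}
for label, name in ((0, "non-seizure"), (1, "seizure")):
    seg = preprocess_segment(gen_segment(spec, label))
    feats[name] = extract_features(seg)
    print(f"{name}: {len(feats[name])} features")
    for key in ("hurstex", "cA4_var", "cD2_rms", "cD1_rms"):
        print(f"  {key:8s} = {feats[name][key]:8.4f}")

print(
    "\nthe 3 Hz spike-and-wave bursts concentrate the unit range on the slow "
    "band: cA4 variance rises in the seizure segment, while the normalized "
    "broadband detail statistics (cD1/cD2 rms) shrink because the background "
    "is compressed relative to the bursts - it is this redistribution, not "
    "raw amplitude, that the classifiers pick up"
)
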