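"""Generate a planted-block benchmark, save it, reload it and summarize it.

The dataset is the standard triple of drug repositioning: drug-drug
similarity, disease-disease similarity and a binary drug-disease
interaction matrix, with matched latent blocks planted so that similar
drugs really do share indications.
"""

from pathlib import Path
from tempfile import TemporaryDirectory

from repogru import SyntheticConfig, generate, load_benchmark, save_benchmark, summarize

cfg = SyntheticConfig(m=80, n=60, k_blocks=4, seed=7)
ds, truth = generate(cfg)

with TemporaryDirectory() as tmp:
    save_benchmark(ds, Path(tmp))
    ds = load_benchmark(Path(tmp))  # round-trips bit-identically for I

s = summarize(ds)
print(f"drugs:        {s.n_drugs}")
print(f"diseases:     {s.n_diseases}")
print(f"interactions: {s.n_interactions}")
print(f"density:      {s.density:.4f}")
print(f"drug blocks:  {sorted(set(truth.drug_blocks))}")

# The density should sit near p_in/k + p_out*(k-1)/k = 0.3/4 + 0.02*3/4 = 0.09:
# each drug-disease pair has a 1/k chance of a block match at rate p_in.
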