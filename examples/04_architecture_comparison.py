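"""Compare the five regression architectures head to head.

Trains, on one shared 80/20 split of a small labeled cohort: a multi-output
network, two single-output networks, the upper-bound network given the true
OXY_V, and the chained model. The chained model approaches the upper bound
without needing any transport solve at inference time, which is the whole
point of the VNQI.
"""

from vnqi import ChainSpec, GeneratorConfig, generate_cohort, split_dataset
from vnqi.model import architecture_comparison
from vnqi.pipeline import build_dataset

masks, prov = generate_cohort(GeneratorConfig(), n=150, master_seed=2)
records = build_dataset(masks, prov)
train, test = split_dataset(records, 0.8, seed=2)

table = architecture_comparison(train, test, ChainSpec(search_budget=4, rng_seed=0))
print(table.round(3).to_string(index=False))
print(
    "\nhigher R2 / lower errors are better; 'oxy_t_with_true_oxy_v' needs the"
    "\nphysics solve at inference, the chained row (VNQI) does not"
)
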