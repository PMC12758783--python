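"""Screen an antibody chain for HLA-II presentation liabilities.

Slides 12-19-mer windows over an antibody sequence, scores every
(window, allele) pair with a trained model, filters prevalent (self-like)
cores and low-probability peptides, and counts the unique surviving cores
per allele - an immunogenicity risk indicator.
"""

import numpy as np

from dscahla import TrainConfig, datasets, tasks
from dscahla.model import Featurizer, PresentationModel
from dscahla.recovery import desk_model_config
from dscahla.training import fit

world = datasets.generate_world(4, 2, seed=41)
pairs = datasets.sample_dataset(world, 300, 5, seed=42)
split = datasets.split_warm_cold(pairs, {world.alleles[-1].name}, seed=43)

cfg = desk_model_config(seed=3)
model = PresentationModel(cfg)
featurizer = Featurizer(cfg)
fit(model, split.train, split.warm_test[:200], world.registry,
    TrainConfig(seed=3, learning_rate=0.3, max_epochs=5, batch_size=32),
    featurizer=featurizer)

# synthetic antibody: background residues with one planted binding core of
# the first allele at offset 30
rng = np.random.default_rng(44)
chain = [tasks.ALPHABET[i] for i in rng.integers(0, 20, size=100)]
pssm = world.core_pssms[world.alleles[0].name]
for j in range(9):
    chain[30 + j] = tasks.ALPHABET[rng.choice(21, p=pssm[j])]
antibody = "".join(chain)
print(f"antibody chain ({len(antibody)} aa), planted core at position 31")
print(f"windows screened: {len(tasks.enumerate_windows(antibody))}")

panel = [a.name for a in world.alleles]
# a user-supplied prevalence table plays the role of a human-repertoire
# database: cores seen in more than 22 subjects are treated as self-like
prevalence = {}
report = tasks.immunogenicity_screen(model, antibody, world.registry,
                                     prevalence, panel=panel, cutoff=0.5)
print(report.to_frame().to_string(index=False))
print(f"total unique presented cores: {report.total_unique_cores}")
# Higher counts mean more distinct peptides of this antibody are predicted
# to be presented by the panel - a higher anti-drug-antibody risk. With an
# empty prevalence table nothing is treated as self-like; supplying real
# subject counts removes the common (tolerated) cores from the tally.
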