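# bsblsel

EEG channel selection for P300 spellers via regionally smoothed
block-sparse Bayesian learning.

P300 spellers decode attended characters from a 6×6 row/column flashing
matrix: the rare attended flashes evoke an event-related potential (the
P300) that a linear classifier detects from epoched multichannel EEG.
Dense caps (59–64 electrodes) carry many channels that add noise rather
than signal; selecting a small informative subset improves accuracy and
comfort.  This package implements a channel-selection algorithm for that
setting, aimed at BCI researchers who want an automatic, training-data-
driven alternative to hand-picked electrode sets.

## The model

Stack each stimulus epoch channel-major into a feature vector
`x ∈ R^D`, `D = N_c·N_t`, and regress the target/non-target label:

    y = Xw + ε,  ε ~ N(0, σ²I)

with a block prior, one block per channel:

    w_b ~ N(0, γ_b B_b),   b = 1 … N_c

* `γ_b ≥ 0` is the channel's relevance; `γ_b = 0` removes the channel.
* `B_b` models the temporal correlation of a channel's weights and is
  constrained to AR(1) Toeplitz form `Toeplitz([1, r, r², …])` with
  `r = m₁/m₀` estimated from the EM statistics.
* **Regional smoothing:** all channels in a spatial scalp region share a
  single `B`, pooling the temporal-correlation estimate over neighbours
  (volume conduction makes adjacent electrodes similar).  A built-in
  13-region 10–20 partition is provided; region files are plain text.

Hyperparameters `(σ², γ, B)` are learned by EM.  The posterior is
computed by whichever of two algebraically equivalent routes inverts the
smaller matrix (`D×D` direct form when `N ≥ D`, `N×N` Woodbury form
otherwise).  After each iteration, channels whose `γ_b` drops below the
shear threshold `τ` are pruned to exactly zero — at most five per
iteration — physically shrinking the model.  Surviving channels with
`γ_b > τ` form the selection; a Bayesian LDA (evidence-maximised
regularised linear discriminant) is then trained on the selected
channels and row/column scores are accumulated into characters.

## Worked example

```python
import numpy as np
from bsblsel import (P300SimSpec, RegionalBSBL, BLDA, gen_p300_session,
                     builtin_region_map, standard_montage, decode_session,
                     accuracy, EpochDataset)

montage = standard_montage(59)
regions = builtin_region_map(montage)

# simulated speller session: 8 informative parieto-occipital channels
ds, truth = gen_p300_session(P300SimSpec(seed=0, n_distractors=10))
train = ds.trial < 9

sel = RegionalBSBL(n_times=ds.n_times, regions=regions, tau=7e-4)
sel.fit(ds.features[train], ds.labels[train],
        channel_names=ds.channel_names)
print(sorted(ds.channel_names[c] for c in sel.selected_channels_))

clf = BLDA().fit(sel.transform(ds.features[train]), ds.labels[train])
test = EpochDataset(features=ds.features[~train], labels=ds.labels[~train],
                    structure=ds.structure, channel_names=ds.channel_names,
                    codes=ds.codes[~train], trial=ds.trial[~train],
                    epoch=ds.epoch[~train])
pred = decode_session(clf.decision_function(sel.transform(test.features)),
                      test, n_epochs_used=2)
true = [ds.true_chars[t] for t in sorted(set(test.trial))]
print(f"{accuracy(pred, true):.1f}% with {len(sel.selected_channels_)} channels")
```

Output:

```
['C2', 'FC5', 'O1', 'O2', 'P3', 'P4', 'P6', 'PO7', 'PO8', 'POz', 'Pz']
100.0% with 11 channels
```

The selection contains all eight planted parieto-occipital channels
(plus three borderline extras) and decodes every test character from two
stimulus repetitions; the same classifier on all 59 channels — including
the ten high-noise distractors — reaches 88.9% at this evidence level.

`RegionalBSBL` is a scikit-learn transformer (`fit`/`transform`/
`get_support`) and `BLDA` a classifier, so both compose with sklearn
pipelines and model selection.  A CLI wraps the library:

```bash
bsblsel simulate --out session.h5 --seed 1
bsblsel select --data session.h5 --out selection.csv --tau 7e-4
bsblsel cv-tau --data session.h5 --grid 1e-4,7e-4,5e-3 --folds 10
bsblsel run --config experiment.yaml
```

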