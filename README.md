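# dmrsq

A scoring engine for the **DMRS-Q**, the Q-sort adaptation of the Defense
Mechanisms Rating Scales — a clinician-report instrument for assessing an
individual's defensive functioning across the full hierarchy of 30 defense
mechanisms.

Defense mechanisms are automatic psychological processes that mediate a
person's reaction to emotional conflict and internal or external stressors.
The DMRS organizes 30 of them into seven adaptiveness levels (L1 action …
L7 high adaptive) and three summary categories (immature, neurotic,
mature). In the Q-sort adaptation a rater files 150 item statements — five
per defense — into a fixed seven-pile forced distribution:

| rank | 1 | 2 | 3 | 4 | 5 | 6 | 7 |
|---|---|---|---|---|---|---|---|
| items | 60 | 30 | 20 | 16 | 10 | 8 | 6 |
| meaning | not used | very rare | rare | sometimes | often | very frequent | almost always |

Because every valid sort carries the same total rank mass
(Σᵢ rank(i) = 384), all quantitative scores are ipsative percentages:

* **Individual defense** D = (Σ of its five item ranks − 5) · 100 / 234,
  where 234 = 384 − 150; the 30 scores always sum to exactly 100.
* **Level** L = sum of member defense scores (plus the hysterical /
  other-neurotic split of L5); **category** C likewise (plus the
  depressive / other-immature split of C1).
* **Overall Defensive Functioning**
  ODF = Σ_L (L/100) · level-number, a weighted mean of defensive mass on
  the 1–7 adaptiveness scale. Over valid sorts ODF ranges from
  553/234 ≈ 2.36 to 1513/234 ≈ 6.47.

The qualitative output is the **Defensive Profile Narrative (DPN)**: the
statements of the 14 items placed in ranks 6–7, each labelled with its
defense and level.

The package provides, as both a library and a `dmrsq` command-line tool:

* the validated 150-item bank and hierarchy (`dmrsq.item_bank`),
* forced-distribution sort representation and validation (`dmrsq.qsort`),
* the full quantitative scoring stack (`dmrsq.scoring`),
* DPN and combined report rendering as JSON / CSV / markdown
  (`dmrsq.report`),
* a synthetic-rater simulator — latent defensive profiles plus Gaussian
  rater noise — producing always-valid sorts (`dmrsq.simulate`),
* inter-rater agreement statistics: ICC(2,1)/ICC(2,k) (two-way random
  effects, absolute agreement) and Q-correlation between sorts, with a
  panel-simulation experiment driver (`dmrsq.reliability`).

## Worked example

Simulate a depressive-leaning subject (latent profile concentrated on
help-rejecting complaining, projection, and devaluation of self-image),
write the sort, and score it:

```python
from dmrsq import load_item_bank, write_sort
from dmrsq.simulate import LatentProfile, RaterModel, profile_sort

bank = load_item_bank()
w = {d: 1.0 for d in bank.defenses}
w.update({"D2": 6.0, "D8": 5.0, "D14": 4.0, "D3": 3.0, "D10": 3.0})
sort = profile_sort(LatentProfile.from_weights(w),
                    RaterModel(noise_sd=0.02, seed=42), bank=bank)
write_sort(sort, "session.csv")
```

```sh
$ dmrsq score session.csv --format md --out report.md
ODF = 3.87; top defenses: Help-rejecting complaining (12.4%), Projection (11.5%), Devaluation of self-image (9.4%)
```

The console summary shows the scoring recovered the latent profile: the
three up-weighted defenses head the list. The ODF of 3.87 falls below 4 —
the range the instrument's interpretive guidance associates with severe
depression or personality pathology — and the report's category block
shows why: 62.8% of defensive mass is immature (C1), 17.5% neurotic (C2),
19.7% mature (C3). `report.md` also contains the 14-sentence DPN and the
45-row scale table (30 defenses, 9 level scales, 5 category scales, ODF).

Validate, simulate panels, and compute agreement from the shell:

```sh
dmrsq validate session.csv                     # exit 0 iff forced distribution holds
dmrsq simulate panel.json --out-dir sorts/     # subjects x raters panel + manifest
dmrsq agreement sorts/ --scales ODF,L7,C1      # ICC per scale
```

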