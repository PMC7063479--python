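# cardiorisk

Proarrhythmic risk stratification of drugs from their ion-channel block
characteristics.

Many drugs — cardiac and non-cardiac alike — block the hERG channel
carrying the rapid delayed rectifier potassium current I_Kr, prolonging
repolarization and promoting early afterdepolarizations (EADs), the
cellular trigger of torsades de pointes. Block of the L-type calcium
current I_CaL has the opposite, protective effect. A drug's risk is
therefore not a single-channel property: it depends on where its
concentration-block characteristics place it in the (I_CaL block,
I_Kr block) plane.

`cardiorisk` implements that idea as a reusable pipeline:

1. **Pore-block model** (`cardiorisk.drugs`). At free concentration `C`
   (nM) a channel with half-block concentration `IC50` is blocked by the
   fraction

       beta = C / (C + IC50),

   and the current is scaled by `(1 - beta)`. Evaluated per channel, a
   drug at a multiple of its effective free therapeutic concentration
   Cmax maps to a point in the unit block square; sweeping concentration
   traces a monotone trajectory. A bundled table supplies IC50 and Cmax
   for 23 reference compounds.
2. **EAD screening** (`cardiorisk.ead`). A pluggable paced cell model
   returns voltage traces; an EAD is flagged when the forward-difference
   slope exceeds 0.1 mV/ms between 50 and 1000 ms after the stimulus in
   either of the last two recorded cycles (600 cycles at 1 Hz by
   default). A deterministic synthetic cell model with an analytically
   known EAD region ships in `cardiorisk.fixtures`.
3. **Channel sensitivity** (`cardiorisk.sensitivity`). 500 simulations
   at Latin-hypercube block combinations of seven channels (0–95%),
   logistic regression on the EAD labels, and normalized average
   marginal effects rank the channels; I_Kr comes out the strongest
   promoter and I_CaL the strongest suppressor.
4. **Boundary learning** (`cardiorisk.gp`). A Bernoulli Gaussian-process
   classifier (RBF kernel, Laplace approximation) learns the
   arrhythmic/safe boundary in the block plane from an expensive binary
   oracle, placing each new query at the point of maximal predictive
   entropy: 10 Latin-hypercube + 30 adaptive queries suffice.
5. **Risk stratification** (`cardiorisk.boundary`). The smallest
   concentration multiple at which a drug's trajectory enters the
   arrhythmic region is its *critical concentration*; trajectories that
   never cross mark safe drugs. Drugs are high risk when the critical
   multiple is at or below 350x Cmax. An analytic surrogate boundary,
   calibrated so that seven reference drugs cross at their known
   critical multiples (with risk onset near 70% I_Kr block and a safe
   wall beyond 60% I_CaL block), supports desk-scale runs; any fitted
   GP boundary plugs into the same interface.

## Worked example

```python
from cardiorisk import bundled_drug_table, block_pair, stratify, surrogate_boundary
from cardiorisk.drugs import drug_by_name

drugs = bundled_drug_table()
terf = drug_by_name(drugs, "terfenadine")
bp = block_pair(terf, 10.0)        # 10x the therapeutic concentration
print(f"I_Kr {100*bp.kr_block:.1f}%  I_CaL {100*bp.cal_block:.1f}%")

report = stratify(drugs, surrogate_boundary(drugs))
print(report.head(3).to_string(index=False))
print(report["category"].value_counts().to_dict())
```

prints

```
I_Kr 83.5%  I_CaL 10.7%
        name  critical_multiple  crossing_cal_block  crossing_kr_block category
thioridazine           0.100000            0.043661           0.642664     high
   quinidine           0.300154            0.038489           0.675490     high
    ajmaline           2.424574            0.029818           0.677231     high
{'high': 14, 'low': 9}
```

Terfenadine at ten times its therapeutic concentration blocks 83.5% of
I_Kr but only 10.7% of I_CaL — a dangerous combination; it crosses the
classification boundary at 3.7x and lands in the high-risk group. The
full table splits into 14 high-risk and 9 low-risk compounds;
thioridazine and quinidine cross at the lowest multiples (0.1x, 0.3x),
while pure calcium blockers such as nitrendipine and verapamil never
cross.

The same pipeline is scriptable from the shell:

```sh
cardiorisk block --drug terfenadine --multiple 10
cardiorisk stratify
cardiorisk sensitivity --n 500 --seed 1
cardiorisk screen-boundary --oracle surrogate-paper --seed 1
cardiorisk run-pipeline --seed 1 --out-dir pipeline_out
```

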