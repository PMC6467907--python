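# breederinvest

A maternal risk-management model of breeder investment, for ecologists and
life-history modellers who want to classify animal species by how breeding
females allocate finite reproductive capital under divergent natural
selection pressures.

## The model

For each species, per breeding event, the model takes offspring quantity *N*,
offspring mass at dispersal *m*, and breeder mass *M*, and computes

- *P* = 1 − *w*/*N* — the probability of offspring mortality by predation
  that a brood of *N* can sustain while still replacing the breeder, where
  *w* = 2 is replacement fitness (one surviving daughter, one outbreeding
  son);
- *S* = *m*/*M* — relative offspring quality, which doubles as the modelled
  probability of offspring mortality by resource scarcity;
- *G* — a bias-corrected Gini coefficient of within-brood investment
  inequality, *G* = (*N*+1)/(*N*−1) − 2/(*N*(*N*−1)µ) · Σᵢ *R*ᵢ*m*ᵢ with
  descending ranks (largest offspring gets rank 1); 0 = equal brood,
  1 = one offspring holds all mass;
- *C* = *P*·*S* — the convergent-selection index, the joint mortality
  product.

Set points on *S* (default 0.1) and *N* (default 10) partition the (*S*, *N*)
plane into four selection categories: **predation** (small cheap offspring in
large clutches — spawning fish, many reptiles, marine invertebrates),
**scarcity** (few expensive offspring — birds, mammals), **weak** (few cheap
offspring — apex predators), and **convergent** (many expensive offspring —
social insects and social mammals). Species breeding a single offspring per
event get *N* replaced by 2.1 before *P* is computed, flagged, so the
probability stays positive. The package also maps categories onto r/K and
CSR selection, draws the quadrant figures with iso-mortality overlays,
generates synthetic species tables with known labels, and ships a seeded
Monte-Carlo harness that measures — under an explicit, package-defined
mortality mechanism — whether joint predation-and-scarcity mortality
(high *C*) favours unequal broods (high *G*). See `docs/methods.md` for
assumptions, parameter semantics, and limitations.

## Worked example

Classify the packaged eight-species demonstration table (illustrative trait
values spanning all four categories):

```
$ breederinvest classify \
    --input src/breederinvest/data/example_species.csv \
    --output classified.csv
category       predation  scarcity  weak  convergent
taxon_group
bird                   0         1     0           0
fish                   1         0     1           0
mammal                 0         1     0           0
reptile                1         0     1           0
social insect          0         0     0           2
classified 8 species
```

`classified.csv` carries the input columns plus `S`, `P`, `C`, `G`,
`category`, `effective_n`, and `singleton_rule_applied`:

```
              species   category        S        P  effective_n  singleton_rule_applied
  gafftopsail_catfish  predation 0.001364 0.963636         55.0                   False
loggerhead_sea_turtle  predation 0.000148 0.982301        113.0                   False
 red_winged_blackbird   scarcity 0.843373 0.428571          3.5                   False
     african_elephant   scarcity 0.200000 0.047619          2.1                    True
    great_white_shark       weak 0.028571 0.666667          6.0                   False
     shedao_pit_viper       weak 0.050000 0.500000          4.0                   False
             fire_ant convergent 0.666667 0.999992     250000.0                   False
            honey_bee convergent 0.555556 0.999987     150000.0                   False
```

Reading the rows: the catfish broods 55 small offspring, so it can lose 96%
of them to predation and still replace its breeder (*P* = 1 − 2/55 = 0.964)
and sits in the predation quadrant; the blackbird's 3.5 fledglings at 84% of
adult mass put it under scarcity selection; the elephant's singleton calf
triggers the *N* → 2.1 substitution (flag `True`, *P* = 1 − 2/2.1 = 0.048);
the two social insects combine huge *N* with near-breeder-sized dispersing
reproductives, the convergent corner. The blackbird's trait cell `3-4` and
the shark's `2-10` are printed ranges, averaged to midpoints on read.

The inequality index from the command line:

```
$ breederinvest gini 3 2 1
0.3333333333333333
```

`breederinvest simulate --output cells.csv --seed 3` runs the conjecture
harness, and `breederinvest plot --input classified.csv --output fig.png
--iso-p 0.9` draws the quadrant scatter with an iso-*P* gridline at
*N* = *w*/(1 − 0.9) = 20.

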