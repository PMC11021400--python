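# rsfpkit

Analysis toolkit for reversibly switchable fluorescent proteins (RSFPs) of
the mSAASoti family: dynamic network analysis of molecular-dynamics
trajectories, chromophore bond-length-alternation (BLA) mixture
decomposition, on-to-off photoswitching kinetics, and the standard
spectroscopic estimators (pKa, extinction coefficient, relative quantum
yield).

Biphotochromic proteins such as mSAASoti combine reversible on/off
photoswitching (chromophore *cis–trans* isomerisation) with irreversible
green-to-red photoconversion.  Whether a given variant can switch depends
on the collective dynamics around the chromophore.  The structural
criterion implemented here is **community co-membership**: build a network
whose nodes are residues (the chromophore split into its imidazolinone,
phenyl and His66-derived fragments), connect two nodes when any pair of
their atoms is closer than 4 Å in more than 75 % of trajectory frames
(sequence neighbours excluded), weight each edge by
*w<sub>ij</sub>* = −log |C<sub>ij</sub>| from the dynamical
cross-correlation matrix, and cut communities by Girvan–Newman edge
betweenness, keeping the partition of maximal modularity *Q*.  A variant is
isomerisation-competent when the phenyl fragment and the His66 fragment
fall in the same community.

The kinetics side fits the off-switching fluorescence decay with the
mono-exponential law

> I(t) = A·exp(−k·t) + c

and derives the switching contrast SC = 100·A/(A + c), rate fold-changes
between variants, and the per-cycle photostability (geometric loss factor
of the initial intensity over repeated switching cycles).  Spectroscopy
adds the single-site Henderson–Hasselbalch pKa fit
A(pH) = A<sub>max</sub>/(1 + 10^(pKa−pH)), the paired-absorbance rule
ε<sub>R</sub> = (ΔA<sub>R</sub>/|ΔA<sub>G</sub>|)·ε<sub>G</sub> for the
red form, and relative quantum yields from dilution-series slope ratios.
The BLA module decomposes the per-frame bond-length alternation of the
chromophore methine bridge into three Gaussians by EM and reports the
right-most component, the phenolic-resonance fraction linked to efficient
isomerisation.

Because the real inputs (hundreds of ns of MD, microscopy time series) are
not shippable, the package includes a first-class synthetic generator
(`rsfpkit.synthgen`) that plants known ground truth with the statistical
structure each estimator assumes — correlated-motion residue groups with
controllable contact geometry, noisy mono-exponential traces with
cycle-to-cycle bleaching, titrations, and three-component BLA mixtures —
so every stage is tested by parameter recovery.

## Worked example

The numbered scripts under `analysis/` run the whole study on synthetic
data (about a minute in total):

```bash
python analysis/01_generate_inputs.py
python analysis/02_network_communities.py
python analysis/03_bla_mixture.py
python analysis/04_switching_kinetics.py
python analysis/05_spectroscopy.py
```

`02_network_communities.py` prints

```
switchable: 2 communities, Q = 0.390, co-membership verdict = True, planted partition recovered = True
non_switchable: 2 communities, Q = 0.455, co-membership verdict = False, planted partition recovered = True
```

— the design that plants the phenyl and His66 fragments in one
correlated-motion group is called isomerisation-competent, the split
design is not, and in both cases the detected communities coincide exactly
with the planted groups.  `04_switching_kinetics.py` refits traces
generated at the published off-switching rates:

```
         variant  k_off_per_s  k_err  switching_contrast_percent
C21N_F177S_green        1.161  0.005                        93.9
C21N_M163A_green        2.293  0.013                        97.0
C21N_M163T_green        3.384  0.021                        98.0
  C21N_M163T_red        1.443  0.006                        97.1
      C21N_green        0.270  0.001                        83.1
fold-change M163T/C21N (green): 12.5 ± 0.1 -> rounds to 13
per-cycle loss factor: 0.815 (planted 0.80)
```

Every fitted rate lands within a percent of its planted value; the
C21N/M163T variant shows the maximal contrast for both forms (98 %/97 %)
and switches 13× faster than C21N.  `05_spectroscopy.py` recovers a
planted pKa of 6.30 as 6.310 ± 0.014, reproduces
ε<sub>R</sub> = 24 ×10³ M⁻¹cm⁻¹ from the 75 ×10³ green value with band
changes −0.75/+0.24, and returns φ = 0.26 from a 0.26/0.59 slope ratio.

A single command runs everything on fresh data and writes a recovery
summary: `rsfpkit demo --seed 0 --outdir demo_out`.  The `rsfpkit` CLI also
exposes the individual stages (`gen`, `network`, `bla`, `kinetics`,
`spectro fit-pka|eps-red|rel-qy`).

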