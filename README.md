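# ipfcm

Quantitative analysis of multi-colour bead immunoassays read out by flow
cytometry (IP-FCM), and a mechanistic kinetic model of proximal T-cell
receptor signalling parameterized from such data.

## The problem

In IP-FCM, antibody-coupled latex beads immunoprecipitate a protein complex
from cell lysate; the captured complex is stained with several
fluorophore-conjugated antibodies and the beads are read on a flow
cytometer. Ratios of background-subtracted geometric mean fluorescence
intensities (MFI) quantify, per captured complex, the amount of an
interaction partner or a phosphorylation site — with replicate errors of a
few percent, roughly ten times tighter than Western blotting. Measuring
calibration beads carrying known numbers of PE fluorophores alongside the
samples converts MFIs into absolute molecules per bead.

Applied to the TCR-CD3 complex, this yields time courses of ZAP70 kinase
recruitment to phosphorylated CD3 ITAMs and of ZAP70 phosphorylation at
Y319, plus absolute stoichiometries (ZAP70 per TCR-CD3, fraction of ZAP70
phosphorylated). These data are precise enough to fit a mechanistic
mass-action model and to expose subtle features such as a transient *drop*
of the pY319-ZAP70/ZAP70 ratio immediately after stimulation.

The package is aimed at quantitative biologists who want a tested,
end-to-end reference implementation: bead-event processing, absolute
calibration, the kinetic model, and the fitting machinery, together with
synthetic-data generators that make every step testable against known
ground truth.

## The model

The modelling unit is a pair of opposing ITAMs (as found on the paired CD3
and ζ chains), because ZAP70 activation-loop phosphorylation (Y493) is a
trans-reaction between two juxtaposed ZAP70 molecules. Each ITAM occupies
one of 7 states:

```
U  →  P1  →  P2  →  Z  →  Z319  →  Z319+493
                              ↘        ↕
                                  Z493
```

(U/P1/P2: 0/1/2 ITAM tyrosines phosphorylated by Lck; Z: ZAP70 docked on
the doubly phosphorylated ITAM via its tandem SH2 domains; Z319, Z493,
Z319+493: phosphorylation marks on the bound ZAP70.) An ordered pair has
7 × 7 = 49 configurations; treating the two ITAMs as indistinguishable
closes the dynamics on 28 unordered states x_i with

    dx/dt = (A_const + g(t) · A_deph) x,    Σ x_i = 1.

All reactions are first-order mass action with the active Lck and free
ZAP70 pools absorbed into the rate constants. The single context-dependent
reaction is Y493 trans-autophosphorylation (rate `k_y493`), active only
when the partner ITAM also carries an opened, pY319-marked ZAP70.
Pervanadate stimulation (phosphatase inhibition) multiplies every
dephosphorylation rate constant by

    g(t) = f_min + (1 − f_min)(1 − exp(−(t − t_dose)/τ_rec)),

which drops to `f_min` at each dose and recovers exponentially. Before the
first dose the system sits in the g ≡ 1 steady state (null vector of the
full-activity generator). Observables are the expected numbers of
ZAP70-bearing and pY319-bearing ITAMs per pair, scaled into arbitrary
fluorescence-ratio units; all parameters are estimated by unweighted
least squares with a simulated-annealing search in log-parameter space.

## Worked example

Absolute stoichiometry from calibrated per-bead counts (16,000 CD3ε, 5,300
ZAP70 and 220 pY319-ZAP70 molecules per bead after 10 min of stimulation,
two CD3ε subunits per TCR-CD3):

```python
from ipfcm import MoleculeCount, molecules_per_complex, phospho_fraction

cd3e = MoleculeCount(16000, 500)
zap  = MoleculeCount(5300, 100)
pzap = MoleculeCount(220, 10)

z  = molecules_per_complex(zap,  cd3e, copies_per_complex=2)
pz = molecules_per_complex(pzap, cd3e, copies_per_complex=2)
f  = phospho_fraction(pzap, zap)
print(f"ZAP70 per TCR-CD3:       {z.value:.3f} +/- {z.sem:.3f}")
print(f"pY319-ZAP70 per TCR-CD3: {pz.value:.4f} +/- {pz.sem:.4f}")
print(f"pY319 fraction of ZAP70: {f.value:.2f}% +/- {f.sem:.2f}%")
```

```
ZAP70 per TCR-CD3:       0.662 +/- 0.024
pY319-ZAP70 per TCR-CD3: 0.0275 +/- 0.0015
pY319 fraction of ZAP70: 4.15% +/- 0.20%
```

So only ~0.66 ZAP70 molecules are bound per TCR-CD3 complex (which could
in principle bind ten), and ~4% of the bound ZAP70 carries pY319.
Uncertainties are first-order (delta-method) propagations of the per-count
standard errors.

Simulating the kinetic model at its reference parameters (single
pervanadate dose at t = 0):

```python
from ipfcm import (RateParameters, StimulationSchedule,
                   simulate_timecourse, compute_observables)

traj = simulate_timecourse(RateParameters(), StimulationSchedule(),
                           [0, 2, 5, 10, 20, 60])
print(compute_observables(traj).round(4).to_string(index=False))
```

```
 time_min  bound_Z  bound_pY319  bound_pY493  ratio
      0.0   0.0541       0.0066       0.0000 0.1228
      2.0   0.1553       0.0106       0.0000 0.0683
      5.0   0.3960       0.0315       0.0000 0.0795
     10.0   0.5462       0.0742       0.0003 0.1358
     20.0   0.4820       0.0953       0.0009 0.1978
     60.0   0.1335       0.0218       0.0000 0.1633
```

Note the characteristic shape: ZAP70 recruitment (`bound_Z`) peaks before
its phosphorylation (`bound_pY319`), and the pY319/ZAP70 `ratio` dips below
its resting value at 2 min — freshly recruited ZAP70 is unphosphorylated
and transiently dilutes the phosphorylated pool — before rising well above
it.

The same operations are exposed on the command line (`ipfcm synth`,
`ipfcm quantify`, `ipfcm calibrate`, `ipfcm stoichiometry`,
`ipfcm simulate`, `ipfcm fit`, `ipfcm predict`); see `ipfcm --help`.

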