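# triplexsim

Simulator for the competition between the murine immune system and
mammary carcinoma under Triplex cancer-vaccine protocols, with a global
sensitivity-analysis pipeline (Latin hypercube sampling + partial rank
correlation coefficients).

## The problem

HER-2/neu transgenic (BALB-neuT) mice develop mammary carcinoma
spontaneously.  The Triplex whole-cell vaccine — engineered tumor cells
presenting the p185 antigen together with allogeneic MHC-I molecules and
IL-12 genes — prevents carcinoma when given on a lifelong ("Chronic")
schedule of 4-week cycles, while a short ("Early") course of three
cycles only delays it.  `triplexsim` models this system as ten coupled
nonlinear ODEs for the entity counts in 1 µl of tissue:

vaccine cells (VC), tumor-associated antigen (TAA), plasma B cells (B),
T helper cells (TH), IL-12, IL-2, antibodies (AB), cancer cells (CC),
cytotoxic T cells (TC) and antigen-presenting cells (APC).

The dynamics are predator–prey-like with mass-action interaction terms
(rates α_ij), release/activation terms (γ_ij), natural death (μ_i), and
saturating interleukin stimulation of lymphocyte duplication of the form
IL/(IL + s).  Cancer cells follow logistic growth k(1 − CC/c_max)·CC
plus a constant transgenic influx p, and are killed by antibodies and
cytotoxic T cells.  Vaccination is an impulsive event: an injection adds
q = 50 vaccine cells at each scheduled 8-hour step (two injections a
week, 3 days apart, in the first two weeks of every 4-week cycle,
starting at week 6 of age).

A simulated mouse is considered dead when CC first reaches 10⁵ cells —
the carcinoma in situ point of no return, beyond which the model is no
longer valid.

## Worked example

```sh
$ triplexsim survival
untreated  death week 14.0
early      death week 46.0
chronic    censored at week 57
```

Without treatment the tumor reaches the 10⁵-cell threshold at 14 weeks
of age.  Three vaccination cycles (Early) raise an antibody response
that suppresses the tumor for months; after the humoral response decays
the tumor regrows and crosses the threshold at 46.0 weeks.  The Chronic
schedule keeps replenishing the response and the mouse never reaches the
threshold within the 57-week horizon.

Single trajectories are written as CSV (one row per 8-hour step):

```sh
triplexsim simulate --protocol early --end-week 57 --out early.csv
```

The sensitivity pipeline samples all immunological parameters (the dose
q and the tumor-growth constants k, p, c_max stay fixed) from ±50%
uniform ranges by Latin hypercube, simulates each draw under the Chronic
protocol, and reports the partial rank correlation of every parameter
with the cancer-cell count week by week, together with a
no-effect "dummy" parameter as a null reference:

```sh
triplexsim sensitivity --n 1000 --seed 1 --out prcc.csv
```

Antibody-related rates (release γ73, killing α87) and the antigen
presentation chain (γ02) correlate negatively with cancer cells
throughout; the cytotoxic-branch rates (γ91, α89) matter only during the
first cycles — the humoral response, not the cytotoxic one, drives
long-term tumor control in this model.

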