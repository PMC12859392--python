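# tacmipd

Model-informed precision dosing (MIPD) of oral tacrolimus for children after
heart transplant. Tacrolimus has a narrow therapeutic window and large
between-patient pharmacokinetic variability, so finding the dose that holds a
child's trough concentration inside the target range (10–14 ng/mL in this
setting) routinely takes many days of trial-and-error titration. `tacmipd`
implements the Bayesian-forecasting core of a clinical decision support tool
for this problem: it individualizes a population pharmacokinetic (popPK)
model to a patient's observed trough concentrations and suggests the dose
that attains a target steady-state trough.

It is aimed at pharmacometricians and clinical-pharmacology researchers; it
consumes a fitted popPK model (it does not estimate population parameters)
and ships only an illustrative demo model — clinical use requires an explicit
model file.

## Model

One-compartment disposition with first-order absorption, parameterized on the
elimination rate constant $k_e$ (1/h), apparent volume $V$ (L, oral
bioavailability absorbed into $V$), and a fixed absorption rate constant
$k_a = 3.43$/h. Between-subject variability is log-normal on $k_e$ and $V$;
residual error on troughs is additive:

$$k_e = \theta_{k_e}\,\left(\tfrac{\mathrm{CrCl}}{\mathrm{CrCl}_{ref}}\right)^{\beta_{crcl}}
\beta_{flu}^{[\mathrm{fluconazole}]}\, e^{\eta_{k_e}},\qquad
V = \theta_V \left(\tfrac{\mathrm{age}}{\mathrm{age}_{ref}}\right)^{\beta_{age}} e^{\eta_V},\qquad
\eta \sim \mathcal N(0, \omega^2).$$

Multi-dose concentration histories (with piecewise-constant, time-varying
covariates) are propagated with the exact closed-form solution of the
depot/central system — no numeric integration. The individual random effects
$(\eta_{k_e}, \eta_V)$ are estimated as the maximum a posteriori (MAP) mode,

$$\mathrm{OFV}(\eta)=\sum_i \frac{(C_{obs,i}-C_{pred,i}(\eta))^2}{\sigma_{add}^2}
+\frac{\eta_{k_e}^2}{\omega_{k_e}^2}+\frac{\eta_V^2}{\omega_V^2},$$

minimized by coordinate descent (bounded 1-D line searches with a
pattern-acceleration step). Because the PK is linear in dose, the dose
attaining a target steady-state trough (operationally: the trough after 200
doses at the stated interval) follows exactly by scaling a unit-dose
prediction, and is cross-checked by re-simulating the full regimen.

Everything is verified against independent brute-force oracles in
`tacmipd.oracle`: an adaptive ODE integrator, a dense-grid objective
minimizer, and a bisection dose solver that share no code with the engine.

## Worked example

`examples/patient_example.csv` holds a patient in the dataset dialect
(`ID,TIME,AMT,DV,AGE,CRCL,FLUC`; TIME in decimal hours since the first dose,
AMT mg on dose rows, DV ng/mL on trough rows, covariates carried forward):
six 1.5 mg doses q12h for a 6-year-old on fluconazole with troughs of 8.4,
9.1 and 10.2 ng/mL.

```sh
tacmipd suggest --data examples/patient_example.csv \
                --model examples/model_illustrative.yaml
```

prints

```
MAP individualization — patient P001
==============================================
eta_ke                 0.379846
eta_V                  0.214528
exp(eta_ke)            1.462059
exp(eta_V)             1.239277
individual ke (1/h)    0.079419
individual V (L)       96.839
objective              1.4918321
sweeps                14
converged             True
observations used     3

Dose recommendation
==============================================
dose (mg)                 1.8090
interval (h)              12
target trough (ng/mL)     12
predicted trough (ng/mL)  12.0000
therapeutic range         10-14 ng/mL
within range              True
```

The fit says this child clears tacrolimus ~46% faster and distributes it into
a ~24% larger apparent volume than a covariate-matched typical patient —
consistent with the observed troughs sitting below target on 1.5 mg — and
1.81 mg every 12 h is predicted to hold the steady-state trough at exactly
12 ng/mL. The same is available programmatically:

```python
from tacmipd import MapIndividualization, load_model, read_dataset

patient = read_dataset("examples/patient_example.csv")[0]
model = load_model("examples/model_illustrative.yaml")
result = MapIndividualization(patient, model).fit()
print(result.summary())
rec = result.suggest_dose(target=12.0, interval=12.0)
print(rec.summary())
```

Other subcommands: `tacmipd fit` (MAP report only), `validate` (in-silico
validation protocol, seeded and deterministic), `simulate` (write a virtual
cohort), `endpoint` (days to three consecutive in-range troughs). The model
config is the flat YAML shown in `examples/model_illustrative.yaml`
(illustrative values, not a clinical model; `ka` defaults to 3.43/h when
omitted).

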