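# cytara

PK/PD modelling of cytarabine (Ara-C)-induced myelosuppression during AML
consolidation therapy: simulation, per-cycle personalisation, cross-validated
prediction, Monte-Carlo uncertainty, and treatment-schedule analysis.

## The problem

Consolidation chemotherapy for acute myeloid leukaemia relies on
intermediate/high-dose Ara-C (1–3 g/m², two 3-h infusions per treatment day).
It causes prolonged leukopenia — circulating white-blood-cell (WBC) counts
below 1 G/L — with a high risk of infection. A mathematical model personalised
to a patient's almost-daily WBC counts can predict the depth and duration of
the suppression and how it would change if the schedule or its timing were
altered.

## The models

The package implements a family of twelve transit-compartment
(Friberg-type) models. A two-compartment drug model with zero-order infusion
input drives the cell dynamics:

    dx1/dt = -(k10 + k12) x1 + k21 x2 + u(t)          (central amount, mg)
    dx2/dt = k12 x1 - k21 x2                           (peripheral amount, mg)

    dx_pr/dt  = F x_pr - G x_pr                        (proliferating cells)
    dx_tr/dt  = G (x_pr - x_tr)                        (n_tr transit stages)
    dx_ma/dt  = G x_tr - k_ma x_ma                     (circulating WBC, G/L)

The drug effect is log-linear in the molar central concentration,
`E = slope·ln(1 + c_V·x1)`, and a secondary saturation term
`S(x1) = 1 + ln(1 + c_V·x1)` distinguishes the extended variants.  The
reference model (M5) uses `F = (1−E)·k_tr·(B/x_ma)^γ` with baseline `B` and
feedback exponent `γ`; the variants swap in a direct kill term (M6), divide
rates by `S` (M7, M8), scale the feedback exponent to `γ·S(x1)` (M9, M10,
M12), or let the feedback act on the bone-marrow pool (M11, M12). Three
initial-condition strategies (steady state / free initial count / fully free,
penalised) complete the grid; see `cytara.models` for the full table.

Personalisation estimates `B, slope, k_tr, γ` (plus initial states) per
consolidation cycle or per patient by multistart penalised least squares on
log-WBC. Schedule analysis compares recovery times `t_rec` (first recovery
above 1 G/L), leukopenia durations `t_leu` and nadirs across the standard
(D135), dense (D123) and low-dose continuous (C100/C400) regimens — the
statistic family on which the model variants can actually be discriminated.

## Worked example

```python
import numpy as np
import cytara as ct

pk = ct.HIDAC_PK                       # high-dose Ara-C PK estimates
consts = ct.ModelConstants.from_pk(pk)
params = ct.PDParameters(b=5.5, slope=5.5, k_tr=0.1875, gamma=0.55,
                         b0=5.5, xpr0=69.7, xtr0=69.7)

for label in ("D123", "D135"):
    sched = ct.build_schedule(label, bsa=1.78)
    traj = ct.simulate_model(ct.get_model("M10"), params, consts, pk,
                             sched, np.arange(0, 45.0, 0.05))
    rs = ct.recovery_stats(traj)
    print(f"{label}: nadir {rs.nadir:.2f} G/L, t_rec {rs.t_rec:.1f} d, "
          f"t_leu {rs.t_leu:.1f} d")
```

prints

```
D123: nadir 0.58 G/L, t_rec 18.6 d, t_leu 8.2 d
D135: nadir 0.29 G/L, t_rec 22.5 d, t_leu 12.0 d
```

i.e. for a typical patient the γ-scaled model (M10) predicts that the dense
D123 schedule recovers about four days *earlier* than the standard D135
schedule — the schedule-discrimination signature that separates M10 from the
reference model M5, which predicts near-identical recovery times.

A `cytara` command-line tool wraps the pipeline (`cytara synth`,
`cytara personalise`, `cytara predict`, `cytara discriminate`,
`cytara timing`, `cytara iiv`, `cytara fit-pk`); all commands read/write the
nine-column NONMEM-dialect CSV described in `cytara.nonmem`.

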