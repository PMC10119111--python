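# nvcsim

A forward simulator of astrocyte-mediated neurovascular coupling.

Functional MRI rests on the coupling between neuronal activity and
cerebral blood flow. `nvcsim` models one biologically concrete route
for that coupling — glutamate spilled from excitatory synapses
activates astrocytic mGluRs, IP3-gated calcium spikes in the astrocyte
drive the arachidonic-acid → prostaglandin-E2 cascade, PGE2 dilates
the nearby arteriole, and the resulting flow change is turned into a
BOLD signal by the Balloon model — and provides the analysis toolkit
to study how stimulus information is coded along the chain.

The model is a deterministic feedforward chain of four stages,
integrated as one coupled ODE system:

1. **Neuronal**: first-order mean field of 10,000 conductance-based
   AdEx neurons (80/20 excitatory/inhibitory, p = 0.05) with
   spike-triggered adaptation,
   `T dnu/dt = F(nu_e + nu_ext, nu_i, W) − nu`,
   `dW/dt = −W/tau_w + b nu_e`; `F` is the semi-analytic
   membrane-moment transfer function with a fitted effective
   threshold. Glutamate: `[Glu] = (g_r nu_e + g_ext nu_ext) p N_e Q_e
   tau_e`.
2. **Astrocyte**: Li-Rinzel calcium dynamics
   (`dCa/dt = J_C + J_L − J_P`, gate `h`) with glutamate-regulated IP3
   turnover (PLCβ + PLCδ production, 3-kinase + 5-phosphatase
   degradation), and Michaelis–Menten production of AA and PGE2.
3. **Vascular**: PGE2-receptor binding → cAMP → arteriole volume
   `CBV_A = 1 + D_A ΔcAMP/(K_VA² + ΔcAMP²)` → inflow
   `CBF = CBV_A^(1/alpha_A)`.
4. **BOLD**: Buxton–Friston Balloon model (venous volume v,
   deoxyhemoglobin q, optional viscoelastic outflow),
   `BOLD = V_0[k1(1−q) + k2(1−q/v) + k3(1−v)]`.

The analysis layer covers calcium-spike statistics (f_Ca, A_Ca),
coding curves with logarithmic and saturating fits, HRF features
(t_ON, t_peak, amplitude, undershoot), double-gamma canonical HRF
fitting, linear convolution prediction from neuronal or calcium
drivers, and the undershoot decompositions (calcium sweep, adaptation
ΔU/U, amplitude clamp).

## Worked example

```sh
python examples/event_hrf.py
```

runs the standard event protocol — a 2 s pulse of external drive at
4 Hz — and prints:

```
calcium spikes: 1 (amplitude 0.56 uM, 2.07 s after onset)
BOLD onset latency t_ON  = 2.21 s
BOLD peak latency t_peak = 5.40 s
peak amplitude           = 1.90 %
post-stimulus undershoot = -0.45 %
total response duration  ~ 30 s
canonical double-gamma fit: d1=5.6 s, d2=15.8 s, R^2=0.999
```

One calcium spike is the minimum activation unit of the response: it
appears ~2 s after the stimulus, drives a flow increase, and yields a
hemodynamic response whose onset (~2 s), peak (~5 s), 1–2% amplitude
and late undershoot match event-related fMRI responses; the
double-gamma fit shows the simulated HRF has the canonical shape used
in fMRI analysis.

Other examples: `block_protocol.py` (block vs event designs),
`coding_curve.py` (frequency/amplitude coding of stimulus intensity),
`adaptation_undershoot.py` (neuronal share of the post-stimulus
undershoot).

A thin CLI mirrors the library:

```sh
nvc run --protocol event --amplitude 4 --duration 2 --out run.csv
nvc run --protocol block --n-stim 10 --duration 2 --isi 1 --t-total 90 --out block.csv
nvc hrf --out hrf.json
nvc coding-curve --out coding.json
nvc dump-defaults --out params.json
```

Parameters live in dataclasses (`nvcsim.params`) and round-trip
through JSON/TOML config files; every constant is overridable.

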