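# s2eir

Deterministic analysis and optimal control of the **S2EIR** compartmental
model of information transmission.

Contact-based transmission of specialised information (practical skills,
technical know-how) behaves much like an epidemic with two peculiarities:
a fraction *m* of transmitters are authoritative "super transmitters" whose
contacts are far more persuasive, and some recipients become "asymptomatic
carriers" — they hold the information but neither use nor pass it on. The
S2EIR model captures this with five compartments: easy adopters *S*,
strongly-receptive hesitants *E₁* (reached through super transmitters),
weakly-receptive carriers *E₂*, active transmitters *I*, and non-adopters
*R*:

```
S'  = B − α(1+m)SI − αSI − μS
E₁' = α(1+m)SI − (β+γ₁+ε+μ)E₁
E₂' = αSI + εE₁ − (γ₂+μ)E₂
I'  = βE₁ − (λ+μ)I
R'  = λI + γ₁E₁ + γ₂E₂ − μR
```

with immigration *B*, contact rate *α*, adoption rate *β*, E₁→E₂ drift *ε*,
drop-out rates *γ₁, γ₂*, removal *μ* and recovery *λ*. The threshold
quantity is the basic reproduction number, the spectral radius of the
next-generation matrix *FV⁻¹*:

```
R₀ = sqrt( Bαβ(1+m) / (μ(β+γ₁+ε+μ)(λ+μ)) )
```

For *R₀ < 1* information dies out (the information-free equilibrium
*E⁰ = (B/μ, 0, 0, 0, 0)* is stable); for *R₀ > 1* a unique positive
information-existence equilibrium *E\** exists in closed form. The package
is aimed at researchers in information/rumor dynamics who want to

- compute *R₀*, both equilibria, closed-form spectra, Routh–Hurwitz
  coefficients and the local/global stability conditions;
- simulate the system with a fixed-step classical Runge–Kutta (RK4) scheme;
- solve the Pontryagin optimal-control problem in which *m(t)* and *β(t)*
  become controls in [0, 1] maximising
  `J = ∫₀^tf [E₁ + I − (c₁/2)m² − (c₂/2)β²] dt`
  via the forward–backward sweep method, and compare control strategies;
- evaluate the sensitivities ∂R₀/∂m and ∂R₀/∂β.

## Worked example

Four scenario parameter sets ship with the package (`set_A` … `set_D`).
`set_B` (B=1, α=0.5, m=0.3, β=0.6, ε=0.2, γ₁=0.5, γ₂=0.7, μ=0.3, λ=0.2) is
the persistence scenario:

```python
import s2eir as s

b = s.get_fixture("set_B").params
print(round(s.basic_reproduction_number(b), 3))     # 1.275
eq = s.information_existence_equilibrium(b)
print(eq.state.round(4))   # [2.0513 0.1359 0.1944 0.163  0.7887]
print(eq.residual)         # 2.78e-17  (max |rhs| at E*)
rep = s.classify_stability(b)
print(rep.thm31_local_E0, rep.thm34_global_Estar)   # False True
```

`R₀ = 1.275 > 1`, so information persists: the closed-form equilibrium
`E* = (S*, E₁*, E₂*, I*, R*)` solves the steady-state equations to
round-off, and the global-stability condition for `E*` (R₀ > 1) holds while
local stability of the extinction state (R₀ < 1) fails. A short
control-strategy comparison on the `set_C` scenario (horizon 10, c₁=c₂=1):

```python
prob = s.OCProblem(params=s.get_fixture("set_C").params, tf=10.0, dt=0.02)
for k, v in s.compare_strategies(prob, ["optimal", "middle", "constant"]).items():
    print(f"{k:10s} J = {v.J:7.4f}")
# optimal    J =  3.8444
# middle     J =  3.1873
# constant   J =  2.8550
```

The swept optimal control beats both the half-effort (*m = β = 0.5*) and
baseline constant policies, as the maximum principle requires.

The same operations are available from the shell:

```bash
s2eir r0        --config src/s2eir/fixtures/set_A.json
s2eir stability --config src/s2eir/fixtures/set_B.json
s2eir simulate  --config src/s2eir/fixtures/set_B.json --tf 50 --out traj.csv
s2eir control   --config src/s2eir/fixtures/set_C.json --out-dir oc/
s2eir sensitivity --config src/s2eir/fixtures/set_B.json --grid 50 --out surf.csv
```

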