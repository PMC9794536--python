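# cytomech

Reduced-order mechanics of single adherent cells — chondrocytes in
particular — under the two workhorse single-cell experiments: **AFM
indentation** (a spherical cantilever tip pressed into the cell) and
**micropipette aspiration** (MPA, negative pressure pulling a surface
projection into a glass pipette).  The package is aimed at cell-mechanics
researchers who want desk-scale, fully scriptable counterparts to the
closed-form models these experiments are analysed with, plus a mechanistic
cytoskeleton model that lets them ask how each subcomponent shifts the
whole-cell response.

Two cell variants are modelled:

* **CM** — a homogeneous viscoelastic continuum (the cytoplasm);
* **CTM** — the continuum combined with a prestressed **tensegrity
  cytoskeleton**: 6 compression struts (microtubules) and 24 tension cables
  (actin microfilaments) meeting at 12 receptor-site junctions, the classic
  expanded-octahedron tensegrity inscribed in the 16 μm cell sphere.

## The models

**Hertz loading.**  During indentation at depth δ,

$$F = \frac{4\,E\,R^{1/2}}{3(1-\nu^2)}\,\delta^{3/2},
\qquad R = \left(\frac{1}{R_\mathrm{cell}} + \frac{1}{R_\mathrm{tip}}\right)^{-1}.$$

**SLS stress relaxation.**  Holding δ fixed, a standard linear solid (spring
$k_1 = E_R$ in parallel with a Maxwell arm) relaxes as

$$F(t) = \frac{4 E_R R^{1/2} \delta^{3/2}}{3(1-\nu)}
\left(1 + \frac{\tau_\sigma - \tau_\varepsilon}{\tau_\varepsilon}
e^{-t/\tau_\varepsilon}\right),$$

with instantaneous and long-term moduli
$E_0 = E_R\,\tau_\sigma/\tau_\varepsilon$ and $E_\infty = E_R(1+\nu)$.
Finite-speed ramps are handled by the hereditary (Lee–Radok-type) integral
$F(t) \propto \int_0^t E(t-s)\,\mathrm d\!\left[\delta^{3/2}(s)\right]$.

**Half-space aspiration.**  The aspirated projection length under a pressure
step ΔP is the viscoelastic creep form

$$L_p(t) = R_p\,\frac{\phi\,\Delta P}{\pi E_1}
\left(1 - \frac{E_2}{E_1+E_2}\,e^{-t/\tau}\right),$$

with punch coefficient φ ≈ 2.1; its elastic limit is the Theret half-space
result $L_p = R_p \phi \Delta P / (\pi E)$.

**Tensegrity cytoskeleton.**  The 12 junctions sit at the cyclic sign
permutations of $(0,\pm1,\pm2)\cdot R_\mathrm{cell}/\sqrt5$; cable/strut
length ratio $\sqrt6/4$, self-stress force densities in ratio
strut:cable $=-3/2$.  A geometrically nonlinear Newton–Raphson solver with
tension-only cables computes its response to indentation and aspiration;
material parameters follow the shipped tables (`celltype1`, `celltype2`,
related by the stiffness ratio Q = 12.78), including linear-elastic ↔
Neo-Hookean conversion $C_{10} = E/(4(1+\nu))$, $D_1 = 6(1-2\nu)/E$.

## Worked example

```python
import cytomech as cm
from cytomech.protocols import CellModel, LoadingProtocol

ct1 = cm.load_material_set("celltype1")
model = CellModel.cm(ct1)
protocol = LoadingProtocol.afm()          # 1.5 um at 9.5 um/s, 60 s hold
curve = cm.simulate_afm(model, protocol)
print(f"peak force      : {curve.y.max():.2f} nN")
print(f"relaxed force   : {curve.y[-1]:.2f} nN")
```

```
peak force      : 4.99 nN
relaxed force   : 2.42 nN
```

The peak is the Hertz-SLS instantaneous response at 1.5 μm depth (the
instantaneous modulus E₀ ≈ 9.33·10⁻⁴ MPa acting through the spherical
contact); over the 60 s hold the force decays toward the relaxed level set
by E_R, with time constant τ_ε = 9.5 s.

Fitting the SLS parameters back from a noisy synthetic relaxation record
closes the loop:

```python
from cytomech.fitting import SLSRelaxationModel, NoiseSpec, generate_synthetic_curve
from cytomech.analytical import equivalent_radius

R_eq = equivalent_radius(8.0, 2.5)
noisy = generate_synthetic_curve(
    "hertz_sls",
    dict(E_R=4.5e-4, tau_sigma=19.7, tau_epsilon=9.5, nu=0.37, R_eq=R_eq, delta=1.5),
    n=600, noise=NoiseSpec(relative_sd=0.05, seed=1),
)
res = SLSRelaxationModel(noisy, nu=0.37, R_eq=R_eq, delta=1.5).fit()
print(res.summary())
```

```
SLS stress relaxation fit
==========================================================
n points:      600    converged: True
residual norm: 0.00328172
----------------------------------------------------------
parameter                   estimate       std err
E_R (MPa)                0.000450762       1.6e-06
tau_sigma (s)                19.1194          0.37
tau_epsilon (s)              9.20722          0.18
----------------------------------------------------------
E0 (MPa)                 0.000936035
E_inf (MPa)              0.000617544
k2 (MPa)                 0.000485273
eta (MPa*s)               0.00446802
==========================================================
```

At 5% multiplicative noise all three generating parameters
(4.5·10⁻⁴ MPa, 19.7 s, 9.5 s) are recovered within a few percent.

The same functionality is available from the shell:

```sh
cytomech material convert --E 1.28e-2 --nu 0.3
cytomech simulate afm --model ctm --out afm_ctm.tsv
cytomech simulate mpa --ratio 2 --dP 1e-4 --out mpa.tsv
cytomech fit relaxation --in relax.tsv --nu 0.37 --Rtip 2.5 --delta 1.5
```

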