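# pivbench

How accurately does particle image velocimetry (PIV) recover the motion of
individual cells when the cells do not follow a viscous flow but move as
coupled stochastic agents?  `pivbench` answers this with a fully synthetic,
ground-truth-controlled pipeline aimed at people who apply PIV to live-cell
imaging of collective migration (wound healing assays, *Dictyostelium*
aggregation, epithelial sheets) and need to choose interrogation-window and
evaluation scales with some justification.

The pipeline has four stages, all seeded and reproducible:

1. **Simulate** N self-propelled particles with the Vicsek model in a
   periodic box of side L: constant speed v₀, and at every step each agent
   adopts the mean heading of all agents within radius r (itself included)
   plus a uniform angular perturbation in [−η₀/2, η₀/2].  The noise
   amplitude η₀ drives the order–disorder transition, monitored by the
   order parameter v_a = |⟨v̂ᵢ⟩| ∈ [0, 1].
2. **Render** each configuration into an 8-bit image (default 615 × 615 px):
   a black 8 × 6-px filled oval per agent, major axis along its heading, on
   a white background, with periodic wrapping.
3. **PIV** between consecutive frames: the image is tiled into γ × γ
   interrogation grids (default 64 px); each grid's patch is matched inside
   a (γ+32) × (γ+32) search zone of the next frame by maximizing the
   normalized cross-correlation C(k, l) over integer offsets |k|, |l| ≤ 16,
   with optional three-point Gaussian sub-pixel refinement and a
   normalized-median outlier test.  Grids with no particle at either time
   produce no vector.
4. **Score** the PIV field against the known agent velocities with the
   alignment score

       A^R = (1/M) Σⱼ (1/N_j^R) Σ_{i: |x⃗ⱼ−x⃗ᵢ|≤R} cos∠(v⃗ⱼ, w⃗ᵢ),

   the mean cosine between each PIV vector v⃗ⱼ and the velocities w⃗ᵢ of the
   agents within radius R of its anchor (A^R = 1: PIV reproduces the local
   motion; 0: unrelated; −1: anti-aligned), plus the local order v_a^R and
   the coherence difference D^R = |v_a^{R,SPP} − v_a^{R,PIV}|.

Two analytic scales organize the results: γ₀(N) = Γ/√N, the grid side that
holds one agent on average in a Γ-px image, and R₀(N) = γ₀/√π, the matching
circle radius.  PIV tracks single-agent motion even at high noise when
γ ≈ γ₀ and R ≈ R₀.

## Worked example

```python
import numpy as np
from pivbench import (VicsekParams, simulate, render_frame, piv_field,
                      alignment_score, order_parameter, gamma0, r0)

params = VicsekParams(eta0=np.pi / 6)        # L=5 (615 px), N=300, v0=3.7 px/frame
traj = simulate(params, 151, seed=7)

f0 = render_frame(traj[150], params)         # 8x6-px black ovals on white
f1 = render_frame(traj[151], params)
field = piv_field(f0, f1)                    # 64-px grids, 96-px search zone

print(f"order parameter v_a(150)      = {order_parameter(traj[150]):.3f}")
print(f"valid PIV vectors             = {field.n_valid} / {len(field.valid)}")
mags = np.linalg.norm(field.vectors[field.valid], axis=1)
print(f"mean PIV displacement         = {mags.mean():.2f} px  (true speed 3.69 px/frame)")
print(f"alignment score A^R (R=30 px) = {alignment_score(field, traj[150], 30.0, params):.3f}")
print(f"gamma0(300), R0(300)          = {gamma0(300, 615):.1f} px, {r0(300, 615):.1f} px")
```

prints

```
order parameter v_a(150)      = 0.984
valid PIV vectors             = 55 / 100
mean PIV displacement         = 3.63 px  (true speed 3.69 px/frame)
alignment score A^R (R=30 px) = 0.991
gamma0(300), R0(300)          = 35.5 px, 20.0 px
```

At this low noise the swarm is almost fully ordered by t = 150
(v_a ≈ 0.98); clustering leaves many grids empty (45 of 100 produce no
vector, by the empty-grid rule), the valid vectors recover the true
3.69-px/frame displacement to within two percent, and the alignment score
at R = 30 px is essentially 1: the PIV field faithfully reports the
underlying agent motion.

## Command line

`pivbench` exposes each stage and the full experiments as subcommands:

```
pivbench simulate --n 300 --eta0 0.5236 --steps 300 --seed 7 --out traj.csv
pivbench render   --traj traj.csv --tau 1 --out frames/
pivbench piv      --frames frames/ --grid 64 --out field.csv
pivbench score    --traj traj.csv --field field.csv --radii 30,70 --out scores.csv
pivbench timeseries | landscape-grid | landscape-noise | sampling-rate | transition
```

Each command writes CSV plus a JSON run manifest (parameters, seeds,
version); stage timings are logged to stderr.

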