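# lampseg — artificial-light-guided underwater object segmentation

Underwater images collected at operational sight distances are dominated by
haze, wavelength-selective attenuation and scattered ambient light; the
color, intensity and contour cues that ordinary segmentation relies on are
largely destroyed. One cue survives: divers and underwater vehicles aim
their lamps at what they care about, so the image region *collimated by
artificial light* is an excellent prior for where the object is. `lampseg`
implements a two-phase method built on that premise, for marine-imaging
researchers and AUV-vision engineers:

1. **Light recognition.** Four per-pixel optical feature maps are computed:
   global intensity contrast `Ci(x) = Σ_y |I_x − I_y|`, channel variation
   `Vc(x) = (r−i)² + (g−i)² + (b−i)²`, an intensity–position map
   `Dd(x) = exp(d(x, m)/d_diag)` around the brightest pixel `m`, and the
   red-channel contrast `Cr` (water removes red fastest, so only lamp light
   is red-rich). Inside a lit region these maps are strongly coupled, and
   the discrimination score multiplies the four couplings:

   `S = corr2(Ci, 1−Dd) · corr2(Ci, Cr) · corr2(Ci, 1−Vc) · corr2(Dd, Vc)`

   Artificial light is declared present when `S > T` (default `T = 0.6`).
   The strength map `W = Ci + Cr − Dd − Vc` is then thresholded with Otsu's
   method and windowed by the largest interior rectangle of the foreground:
   the candidate object region.

2. **Kernel graph-cut segmentation.** Inside the window, a binary labeling
   `v` and per-region model values `{u_l}` minimize

   `ψ({u_l}, v) = Σ_l Σ_{p∈R_l} ‖φ(u_l) − φ(I_p)‖² + α Σ_{{p,q}∈N} min((v(p)−v(q))², r_max)`

   with an RBF kernel `φ` (so the data term is `2(1 − exp(−‖u−I‖²/σ²))`,
   bounded and outlier-robust) and 4-connected smoothness. Minimization
   alternates exact closed-loop stages: fixed-point model updates, then an
   exact s/t min-cut for the optimal labeling. The energy trace is
   guaranteed non-increasing.

Because the public benchmarks for this problem are not redistributable, the
package ships a first-class synthetic scene generator
(`lampseg.synthetic`) that renders the relevant optics — a collimated beam
with a flat core, lamp-axis hot spot and exponential edge halo, local red
restoration, blue-green haze growing with distance from the lamp, textured
background, noise — with exact ground-truth masks, reproducible from a seed.

## Worked example

```sh
python examples/03_segmentation_pipeline.py
```

```
discrimination score S = 0.7013 -> artificial light: True
candidate window: RectWindow(row0=39, col0=45, row1=89, col1=82) (Otsu threshold 0.3000)
guided:   1 iterations, energy 277.1 -> 272.4, IoU vs planted object = 0.995
unguided: IoU vs planted object = 0.192
```

`S = 0.70 > 0.6`: the lamp is recognized, the candidate window is the
bright beam zone, and the graph cut inside it recovers the planted object
almost exactly (IoU 0.995). The same minimizer run on the whole image
without guidance latches onto the bright beam region instead of the object
and collapses to IoU 0.19 — the value of the light prior in one number.
The other examples (`examples/01…04`) demonstrate scene generation, the
feature maps and score factors, and the evaluation criteria.

## Library and CLI

Everything is importable from the top level (`generate_scene`,
`compute_feature_maps`, `recognize_light`, `identify_candidate`, `segment`,
`evaluate_masks`, …). A thin CLI wraps the pipeline:

```sh
lampseg segment IMAGE.png --out results/       # masks + JSON artifacts
lampseg evaluate PRED_DIR TRUTH_DIR            # per-image + mean criteria CSV
lampseg make-fixtures -n 5 --seed 0 --out fx/  # synthetic scenes to disk
lampseg features IMAGE.png                     # debug: export feature maps
```

`lampseg segment` exits with code 3 (not an error) when no artificial light
is recognized and `--no-fallback` is set; otherwise it segments the whole
image and tags the output `unguided`.

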