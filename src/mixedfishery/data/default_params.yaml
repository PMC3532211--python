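# Default parameter set for the sole/plaice mixed-fishery model.
# One block per species, one for the shared resource base.
# Units: lengths cm, weights g, densities g L^-1, rates d^-1,
# ingestion/maintenance g g^-1 d^-1, prices EUR kg^-1.
resources:
  r: 0.1            # resource regrowth rate
  K_m: 0.3          # sole-side resource maximum (split by omega)
  K_p: 1.0          # plaice exclusive resource maximum (3 * K_m)
  R_h: 0.01         # feeding half-saturation constant
  omega: 0.0        # resource overlap fraction (scenario setting)
species:
  plaice:
    L_J: 1.5        # size at settlement
    L_LJ: 10.0      # size at catch (minimum size retained by gear)
    L_A: 27.0       # size at landing (= maturation size)
    lw_a: 0.0089    # length-weight W = a L^b
    lw_b: 3.0353
    W_avg: {J: 1.7, LJ: 65.5, A: 208.6}
    L_avg: {J: 5.6, LJ: 18.5, A: 27.0}
    I_max: {J: 0.069, LJ: 0.020, A: 0.013}
    z: {J_LJ: 0.003, LJ_A: 0.048}
    T: 0.0037       # maintenance rate
    delta: 0.36     # food conversion factor
    mu: 0.001       # background mortality
    price: 1.38
    f: {LJ: 5.0e-5, A: 0.001272}   # catchabilities
  sole:
    L_J: 0.85
    L_LJ: 12.0
    L_A: 24.0
    lw_a: 0.0091
    lw_b: 3.077
    W_avg: {J: 2.3, LJ: 66.4, A: 160.7}
    L_avg: {J: 6.1, LJ: 18.0, A: 24.0}
    I_max: {J: 0.050, LJ: 0.016, A: 0.011}
    z: {J_LJ: 0.0003, LJ_A: 0.118}
    T: 0.0032
    delta: 0.36
    mu: 0.001
    price: 10.06
    f: {LJ: 2.0e-6, A: 0.001455}
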