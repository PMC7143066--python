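# Water-ethanol binary mixture properties at 25 C versus ethanol mass
# fraction w. Values compiled (approximate, to ~1-2%) from standard published
# measurement tables for the binary system: mixture density and dynamic
# viscosity from pycnometry/viscometry compilations, mutual diffusion
# coefficient from Taylor-dispersion/diaphragm-cell data (note the
# characteristic minimum near w ~ 0.4). Intended to be fitted with order-5
# polynomials; users may override with their own table or coefficients.
# Columns: w (ethanol mass fraction), density_kg_m3, viscosity_mpa_s,
# diffusivity_1e9_m2_s.
w,density_kg_m3,viscosity_mpa_s,diffusivity_1e9_m2_s
0.0,997.05,0.890,1.23
0.1,981.64,1.280,0.90
0.2,968.64,1.760,0.66
0.3,953.71,2.090,0.48
0.4,935.34,2.310,0.40
0.5,913.82,2.370,0.42
0.6,891.12,2.240,0.51
0.7,867.85,1.990,0.64
0.8,843.75,1.700,0.80
0.9,818.06,1.370,0.96
1.0,785.22,1.070,1.10
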