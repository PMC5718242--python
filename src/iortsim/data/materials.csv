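# Bundled material constants, frozen from standard compilations (densities,
# mean excitation energies, radiation lengths, Sternheimer density-effect
# coefficients). Units are stated in the column headers.
name,density_g_cm3,z_over_a,effective_z,mean_excitation_energy_ev,radiation_length_g_cm2,sternheimer_cbar,sternheimer_x0,sternheimer_x1,sternheimer_a,sternheimer_k,sternheimer_delta0,electron_cutoff_kev,photon_cutoff_kev,is_gas
water,1.000,0.55509,7.42,79.7,36.08,3.5017,0.2400,2.8004,0.09116,3.4773,0.0,25,10,0
pmma,1.190,0.53937,6.56,74.0,40.55,3.3297,0.1824,2.6681,0.11433,3.3836,0.0,25,10,0
aluminum,2.699,0.48181,13.0,166.0,24.01,4.2395,0.1708,3.0127,0.08024,3.6345,0.12,25,10,0
lead,11.35,0.39575,82.0,823.0,6.37,6.2018,0.3776,3.8073,0.09359,3.1608,0.14,12,10,0
titanium,4.540,0.45948,22.0,233.0,16.16,4.4450,0.0957,3.0386,0.15662,3.0302,0.12,25,10,0
air,0.0012048,0.49919,7.64,85.7,36.62,10.5961,1.7418,4.2759,0.10914,3.3994,0.0,25,10,1
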