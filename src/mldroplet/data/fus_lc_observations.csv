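# protein: FUS-LC
# rho_c_mgml: 527
# source: finite-size NVT nucleation campaign (cubic boxes, 300 K, 100 mM)
# flags: stable = steady droplet; fluctuating = unstable/multiple droplets; none = no phase separation
system,L_nm,N,rho0_nm3,rho0_mgml,nss,nss_err,flag
FUS-LC-1,40,25,0.00039,11.1,,,none
FUS-LC-2,40,35,0.00055,15.7,,,fluctuating
FUS-LC-3,40,50,0.00078,22.3,42,0.5,stable
FUS-LC-4,50,49,0.00039,11.1,,,fluctuating
FUS-LC-5,50,69,0.00055,15.7,55,1,stable
FUS-LC-6,50,98,0.00078,22.3,86,1,stable
FUS-LC-7,60,84,0.00039,11.1,63,1,stable
FUS-LC-8,60,118,0.00055,15.7,101,1,stable
FUS-LC-9,60,169,0.00078,22.3,153,1,stable
FUS-LC-10,70,133,0.00039,11.1,103,2,stable
FUS-LC-11,70,187,0.00055,15.7,158,1,stable
FUS-LC-12,70,268,0.00078,22.3,243,2,stable
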