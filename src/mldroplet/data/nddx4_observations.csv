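# protein: NDDX4
# rho_c_mgml: 359
# source: finite-size NVT nucleation campaign (cubic boxes, 300 K, 100 mM)
# flags: stable = steady droplet; fluctuating = unstable/multiple droplets; none = no phase separation
system,L_nm,N,rho0_nm3,rho0_mgml,nss,nss_err,flag
NDDX4-1,40,25,0.00039,16.5,,,none
NDDX4-2,40,35,0.00055,23.2,,,fluctuating
NDDX4-3,40,50,0.00078,32.9,,,fluctuating
NDDX4-4,50,49,0.00039,16.5,,,fluctuating
NDDX4-5,50,69,0.00055,23.2,45,2,stable
NDDX4-6,50,98,0.00078,32.9,76,2,stable
NDDX4-7,60,84,0.00039,16.5,42,2,stable
NDDX4-8,60,118,0.00055,23.2,84,3,stable
NDDX4-9,60,169,0.00078,32.9,139,2,stable
NDDX4-10,70,133,0.00039,16.5,71,2,stable
NDDX4-11,70,187,0.00055,23.2,130,3,stable
NDDX4-12,70,268,0.00078,32.9,214,2,stable
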