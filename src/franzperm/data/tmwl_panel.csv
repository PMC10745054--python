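membrane,formulation,tmwl
nuclepore,control,80.8
mucosa,control,72.4
nuclepore,F01 Tea tree mouthwash,71.3
nuclepore,F02 Semisolid anhydrous absorption base,15.98
nuclepore,F03 Lipophilic base MI,2.6
nuclepore,F04 Lipophilic base TGCM,3.6
nuclepore,F05 Fluid anhydrous absorption base,22.5
nuclepore,F06 Sodium carboxymethyl cellulose gel 4%,64.6
nuclepore,F07 Sodium hyaluronate gel 2%,75.4
nuclepore,F08 Chitosan gel 2%,75.2
nuclepore,F09 Alginate gel 4%,74.5
nuclepore,F10 Gel PLX-CBP,74.8
nuclepore,F11 PC 10%,57.8
nuclepore,F12 HPC 10%,68.0
nuclepore,F13 Cer3 1%,59.3
nuclepore,F14 Cer3 10%,57.2
nuclepore,F15 Cer3Cer6 1%,49.2
nuclepore,F16 Cer3Cer6 10%,50.4
mucosa,F01 Tea tree mouthwash,58.5
mucosa,F02 Semisolid anhydrous absorption base,23.6
mucosa,F03 Lipophilic base MI,6.5
mucosa,F04 Lipophilic base TGCM,3.0
mucosa,F05 Fluid anhydrous absorption base,34.2
mucosa,F06 Sodium carboxymethyl cellulose gel 4%,53.8
mucosa,F07 Sodium hyaluronate gel 2%,59.3
mucosa,F08 Chitosan gel 2%,63.0
mucosa,F09 Alginate gel 4%,62.9
mucosa,F10 Gel PLX-CBP,57.0
mucosa,F11 PC 10%,66.1
mucosa,F12 HPC 10%,63.7
mucosa,F13 Cer3 1%,65.6
mucosa,F14 Cer3 10%,60.8
mucosa,F15 Cer3Cer6 1%,47.2
mucosa,F16 Cer3Cer6 10%,45.1
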