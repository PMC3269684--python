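tag,description,specification,cost_kusd,section
V-101,Flat Bottom Tank,Volume = 1006.5 L,28,reaction
P-4,Centrifugal Pump,Power = 0.04 kW,9,reaction
P-3,Gear Pump,Power = 0.12 kW,1,reaction
V-103,Stirred Reactor,Volume = 2.05 m3,1094,reaction
HX-102,Heat Exchanger,Area = 0.15 m2,1,reaction
CFUGE,Disk-Stack Centrifuge,Throughput = 919 L/h,450,separation
SDR-107,Spray Dryer,Volume = 7.61 m3,897,separation
DDR-108,Drum Dryer,Area = 1.36 m2,370,separation
G-106,Centrifugal Compressor,Power = 99.8 HP,400,reaction
V-105,Blending Tank,Volume = 0.46 m3,169,separation
UNLISTED,Unlisted Equipment,,603,shared
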