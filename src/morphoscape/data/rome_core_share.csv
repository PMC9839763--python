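function,share_1949,share_1974,share_1999,share_2016,rate_urbanisation,rate_suburbanisation,rate_counter_urbanisation
built_up,34.9,42.2,36.9,35.5,0.84,-0.51,-0.21
urban_green,30.5,27.2,19.5,19.2,-0.42,-1.13,-0.1
arable,61.6,50.4,37.4,35.4,-0.73,-1.03,-0.3
crop_mosaic,17.1,16.3,4.2,5.4,-0.2,-2.98,1.68
vineyards,42.9,32.5,8.7,8.5,-0.97,-2.93,-0.17
olive_groves,14.0,7.6,1.7,3.1,-1.83,-3.12,5.15
woodland,36.6,34.6,29.2,29.2,-0.22,-0.63,0.01
pastures,25.2,23.5,6.9,6.5,-0.28,-2.82,-0.34
wetlands,1.6,2.4,2.2,2.1,2.1,-0.35,-0.13
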