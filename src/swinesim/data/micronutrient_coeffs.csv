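nutrient,class,intercept,slope,units
sodium,mineral,-2.3336226045751123,1.0862645212190558,g/d
chlorine,mineral,-1.7907456985248293,0.8472008775879221,g/d
magnesium,mineral,-1.4768113022875593,0.5431322606095287,g/d
potassium,mineral,0.6492543014752811,0.8472008775878987,g/d
copper,mineral,-1.2154257932870856,1.9984703721542703,mg/d
iodine,mineral,0.4000000000000025,-5.258317441493223e-16,mg/d
iron,mineral,34.57870863407733,15.85775303053963,mg/d
manganese,mineral,-5.038302699337256,2.2375340157853807,mg/d
selenium,mineral,-0.7428769060502611,0.2390636436311294,mg/d
zinc,mineral,-70.29408000137882,43.64132332065719,mg/d
vitamin_a,vitamin,-3358.078746628684,1472.097283036637,IU/d
vitamin_d3,vitamin,-386.80472272041436,169.72115166073195,IU/d
vitamin_e,vitamin,-28.478308571823085,12.46894952018789,IU/d
vitamin_k,vitamin,-1.1868113022875622,0.5431322606095292,mg/d
biotin,vitamin,0.14000000000000032,-6.685859532982372e-17,mg/d
choline,vitamin,-0.2928769060502597,0.23906364363112906,g/d
folacin,vitamin,-0.2928769060502597,0.23906364363112906,mg/d
niacin,vitamin,-77.72194292136837,34.01804505021165,mg/d
pantothenic_acid,vitamin,-11.763088682148611,6.538543377072297,mg/d
riboflavin,vitamin,-1.1375570008124563,1.3903331381974642,mg/d
thiamin,vitamin,-2.3636226045751094,1.0862645212190551,mg/d
vitamin_b6,vitamin,-2.3636226045751094,1.0862645212190551,mg/d
vitamin_b12,vitamin,16.610745698524696,-0.8472008775878939,ug/d
linoleic_acid,vitamin,-2.3636226045751094,1.0862645212190551,g/d
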