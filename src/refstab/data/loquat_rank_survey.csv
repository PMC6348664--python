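subset,gene,delta_ct,bestkeeper,normfinder,genorm,consensus,consistent
All samples,RPL4,1,5,2,1,1.78,1
All samples,RPL18,2,3,4,1,2.21,1
All samples,HIS3,3,1,3,4,2.45,1
All samples,TUA3,4,2,1,6,2.63,1
All samples,SAMDC,11,11,11,11,11.00,1
All samples,TIP41,6,4,7,3,4.74,1
All samples,UGPase,8,6,8,7,7.20,1
All samples,18S,9,9,9,9,9.00,1
All samples,GAPDH,7,8,6,8,7.20,1
All samples,PIP2,10,10,10,10,10.00,1
All samples,ACT,5,7,5,5,5.44,1
Fruits,RPL4,5,6,4,7,5.38,1
Fruits,RPL18,1,3,1,4,1.86,1
Fruits,HIS3,6,8,7,3,5.63,1
Fruits,TUA3,7,5,5,8,6.12,1
Fruits,SAMDC,11,11,11,11,11.00,1
Fruits,TIP41,4,9,6,1,3.83,1
Fruits,UGPase,9,2,9,9,6.18,1
Fruits,18S,3,7,3,5,4.21,1
Fruits,GAPDH,2,1,2,6,2.21,1
Fruits,PIP2,10,4,10,10,7.95,1
Fruits,ACT,8,10,8,1,5.03,1
Floral tissues,RPL4,5,10,5,5,5.95,1
Floral tissues,RPL18,2,2,2,1,1.68,1
Floral tissues,HIS3,3,1,3,1,1.73,1
Floral tissues,TUA3,8,9,7,9,8.21,1
Floral tissues,SAMDC,11,11,11,11,11.00,1
Floral tissues,TIP41,7,6,8,4,6.05,1
Floral tissues,UGPase,1,1,1,3,1.86,0
Floral tissues,18S,9,3,9,7,6.42,1
Floral tissues,GAPDH,6,8,6,6,6.45,1
Floral tissues,PIP2,10,7,10,10,9.15,1
Floral tissues,ACT,4,5,4,8,5.03,1
Ovules and seeds,RPL4,8,7,8,5,6.88,1
Ovules and seeds,RPL18,7,3,7,3,4.58,1
Ovules and seeds,HIS3,9,9,9,9,9.00,1
Ovules and seeds,TUA3,2,4,2,4,2.83,1
Ovules and seeds,SAMDC,5,1,6,1,2.34,1
Ovules and seeds,TIP41,1,2,1,1,1.19,1
Ovules and seeds,UGPase,10,10,10,10,10.00,1
Ovules and seeds,18S,4,6,5,8,5.57,1
Ovules and seeds,GAPDH,6,8,4,7,6.05,1
Ovules and seeds,PIP2,11,11,11,11,11.00,1
Ovules and seeds,ACT,3,5,3,6,4.05,1
Vegetative tissues,RPL4,2,4,2,3,2.63,1
Vegetative tissues,RPL18,1,1,1,4,1.41,1
Vegetative tissues,HIS3,7,5,7,6,6.19,1
Vegetative tissues,TUA3,4,2,3,5,3.31,1
Vegetative tissues,SAMDC,11,9,11,11,10.46,1
Vegetative tissues,TIP41,3,6,4,1,2.91,1
Vegetative tissues,UGPase,5,8,5,7,6.12,1
Vegetative tissues,18S,9,11,9,10,9.72,1
Vegetative tissues,GAPDH,10,7,10,9,8.91,1
Vegetative tissues,PIP2,8,3,8,8,6.26,1
Vegetative tissues,ACT,6,10,6,1,4.36,1
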